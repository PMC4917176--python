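# canonical	rtype	source[	expansion]
BLAST	SW	curated
BLAT	SW	curated
FASTA	SW	curated
HMMER	SW	curated
DIAMOND	SW	curated
Bowtie	SW	curated
Bowtie2	SW	curated
BWA	SW	curated
SOAP	SW	curated
SOAP2	SW	curated
TopHat	SW	curated
STAR	SW	curated
HISAT	SW	curated
GSNAP	SW	curated
MAQ	SW	curated
Stampy	SW	curated
Novoalign	SW	curated
minimap2	SW	curated
ClustalW	SW	curated
ClustalX	SW	curated
Clustal Omega	SW	curated
MUSCLE	SW	curated
MAFFT	SW	curated
T-Coffee	SW	curated
Kalign	SW	curated
DIALIGN	SW	curated
ProbCons	SW	curated
PRANK	SW	curated
Velvet	SW	curated
ABySS	SW	curated
SOAPdenovo	SW	curated
SPAdes	SW	curated
Trinity	SW	curated
Oases	SW	curated
ALLPATHS	SW	curated
Newbler	SW	curated
MIRA	SW	curated
Canu	SW	curated
Celera Assembler	SW	curated
Phrap	SW	curated
CAP3	SW	curated
GATK	SW	curated
Picard	SW	curated
SAMtools	SW	curated
BCFtools	SW	curated
VarScan	SW	curated
ANNOVAR	SW	curated
SnpEff	SW	curated
FreeBayes	SW	curated
PLINK	SW	curated
IMPUTE2	SW	curated
SHAPEIT	SW	curated
Beagle	SW	curated
VCFtools	SW	curated
BEDTools	SW	curated
Tabix	SW	curated
Cufflinks	PK	curated
Cuffdiff	PK	curated
HTSeq	PK	curated
featureCounts	PK	curated
StringTie	PK	curated
Kallisto	PK	curated
Salmon	PK	curated
RSEM	PK	curated
DESeq	PK	curated
DESeq2	PK	curated
edgeR	PK	curated
limma	PK	curated
voom	PK	curated
Ballgown	PK	curated
PHYLIP	SW	curated
PAUP	SW	curated
MrBayes	SW	curated
RAxML	SW	curated
PhyML	SW	curated
MEGA	SW	curated
BEAST	SW	curated
TreeView	SW	curated
FigTree	SW	curated
iTOL	SW	curated
Dendroscope	SW	curated
SplitsTree	SW	curated
Mesquite	SW	curated
Jalview	SW	curated
PyMOL	SW	curated
Chimera	SW	curated
VMD	SW	curated
Coot	SW	curated
Phenix	SW	curated
CCP4	SW	curated
Modeller	SW	curated
I-TASSER	SW	curated
Rosetta	SW	curated
AutoDock	SW	curated
GROMACS	SW	curated
AMBER	SW	curated
CHARMM	SW	curated
NAMD	SW	curated
ImageJ	SW	curated
Fiji	SW	curated
CellProfiler	SW	curated
Imaris	SW	curated
MetaMorph	SW	curated
Mascot	SW	curated
SEQUEST	SW	curated
MaxQuant	SW	curated
Skyline	SW	curated
Xcalibur	SW	curated
OpenMS	SW	curated
X!Tandem	SW	curated
Proteome Discoverer	SW	curated
Scaffold	SW	curated
Progenesis	SW	curated
R	SW	curated
Bioconductor	SW	curated
SPSS	SW	curated
Stata	SW	curated
SAS	SW	curated
MATLAB	SW	curated
Octave	SW	curated
Mathematica	SW	curated
GraphPad Prism	SW	curated
Microsoft Excel	SW	curated
Origin	SW	curated
SigmaPlot	SW	curated
Minitab	SW	curated
JMP	SW	curated
Python	SW	curated
Perl	SW	curated
BioPerl	SW	curated
Biopython	SW	curated
WEKA	SW	curated
KNIME	SW	curated
RapidMiner	SW	curated
Orange	SW	curated
Galaxy	SW	curated
Taverna	SW	curated
Kepler	SW	curated
Snakemake	SW	curated
Cytoscape	SW	curated
Gephi	SW	curated
Circos	SW	curated
IGV	SW	curated
Tablet	SW	curated
Artemis	SW	curated
GBrowse	SW	curated
JBrowse	SW	curated
UCSC Genome Browser	SW	curated
Integrative Genomics Viewer	SW	curated
Primer3	SW	curated
BioEdit	SW	curated
Geneious	SW	curated
Vector NTI	SW	curated
CLC Genomics Workbench	SW	curated
DNASTAR	SW	curated
Lasergene	SW	curated
MACS	SW	curated
HOMER	SW	curated
MEME	SW	curated
TRANSFAC	SW	curated
JASPAR	SW	curated
FastQC	SW	curated
Trimmomatic	SW	curated
cutadapt	SW	curated
PRINSEQ	SW	curated
SeqPrep	SW	curated
GenBank	DB	curated
RefSeq	DB	curated
EMBL	DB	curated
DDBJ	DB	curated
UniProt	DB	curated
SWISS-PROT	DB	curated
TrEMBL	DB	curated
UniRef	DB	curated
Ensembl	DB	curated
Entrez	DB	curated
PubMed	DB	curated
MEDLINE	DB	curated
ClinicalTrials.gov	DB	curated
dbSNP	DB	curated
dbGaP	DB	curated
ArrayExpress	DB	curated
Reactome	DB	curated
BioCyc	DB	curated
EcoCyc	DB	curated
MetaCyc	DB	curated
WikiPathways	DB	curated
STRING	DB	curated
BioGRID	DB	curated
IntAct	DB	curated
MINT	DB	curated
DIP	DB	curated
HPRD	DB	curated
FlyBase	DB	curated
WormBase	DB	curated
ZFIN	DB	curated
Xenbase	DB	curated
RGD	DB	curated
HGNC	DB	curated
HapMap	DB	curated
ENCODE	DB	curated
Pfam	DB	curated
InterPro	DB	curated
PROSITE	DB	curated
PRINTS	DB	curated
ProDom	DB	curated
SUPERFAMILY	DB	curated
Gene3D	DB	curated
PIRSF	DB	curated
TIGRFAMs	DB	curated
CDD	DB	curated
COG	DB	curated
miRBase	DB	curated
Rfam	DB	curated
SILVA	DB	curated
Greengenes	DB	curated
RDP	DB	curated
IMG	DB	curated
MG-RAST	DB	curated
PATRIC	DB	curated
PharmGKB	DB	curated
DrugBank	DB	curated
ChEMBL	DB	curated
PubChem	DB	curated
ZINC	DB	curated
PRIDE	DB	curated
PeptideAtlas	DB	curated
ProteomeXchange	DB	curated
GPMDB	DB	curated
MassBank	DB	curated
Metlin	DB	curated
HMDB	DB	curated
LIPID MAPS	DB	curated
GO	DB	curated	Gene Ontology
PDB	DB	curated	Protein Data Bank
KEGG	DB	curated	Kyoto Encyclopedia of Genes and Genomes
GEO	DB	curated	Gene Expression Omnibus
SRA	DB	curated	Sequence Read Archive
OMIM	DB	curated	Online Mendelian Inheritance in Man
MGD	DB	curated	Mouse Genome Database
SGD	DB	curated	Saccharomyces Genome Database
TAIR	DB	curated	The Arabidopsis Information Resource
SCOP	DB	curated	Structural Classification of Proteins
CATH	DB	curated	Class Architecture Topology Homology
SMART	DB	curated	Simple Modular Architecture Research Tool
TCGA	DB	curated	The Cancer Genome Atlas
ICGC	DB	curated	International Cancer Genome Consortium
CCDS	DB	curated	Consensus Coding Sequence
VISTA	DB	curated	Visualization Tool for Alignments
MAGE	DB	curated	MicroArray Gene Expression
BioPAX	DB	curated	Biological Pathway Exchange
Gene Ontology	ONT	curated
Sequence Ontology	ONT	curated
Human Phenotype Ontology	ONT	curated
ChEBI	ONT	curated
Disease Ontology	ONT	curated
Cell Ontology	ONT	curated
Plant Ontology	ONT	curated
MeSH	ONT	curated
SNOMED CT	ONT	curated
UMLS	ONT	curated
FMA	ONT	curated
NCBI Taxonomy	ONT	curated
OBO Foundry	ONT	curated
Cluster	SW	curated-ambiguous
Match	SW	curated-ambiguous
Prism	SW	curated-ambiguous
Oracle	SW	curated-ambiguous
Express	SW	curated-ambiguous
Mosaic	SW	curated-ambiguous
Phoenix	SW	curated-ambiguous
Compass	SW	curated-ambiguous
Beacon	SW	curated-ambiguous
Horizon	SW	curated-ambiguous
Summit	SW	curated-ambiguous
Fusion	SW	curated-ambiguous
Gateway	SW	curated-ambiguous
Cascade	SW	curated-ambiguous
Spectrum	SW	curated-ambiguous
Anchor	SW	curated-ambiguous
Catalyst	SW	curated-ambiguous
Sentinel	SW	curated-ambiguous
Pulse	SW	curated-ambiguous
Vertex	SW	curated-ambiguous
analysis	SW	curated-ambiguous
genomes	SW	curated-ambiguous
cell	SW	curated-ambiguous
smart	SW	curated-ambiguous
image	SW	curated-ambiguous
focus	SW	curated-ambiguous
trace	SW	curated-ambiguous
scan	SW	curated-ambiguous
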