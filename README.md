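# resmine

Mining database and software mentions from biomedical full text.

Computer-based resources — databases such as GenBank, software such as BLAST
or R, packages and ontologies — are the working capital of modern biology,
yet which ones a community actually uses is hard to see: citations
under-count usage, and registries go stale. `resmine` takes the text-mining
route: it recognises resource *name mentions* directly in full-text articles
and turns the extracted mention stream into a usage survey — who uses what,
where in the paper, in which journals and sub-disciplines, and how usage
shifts over the years. It is aimed at meta-scientists, bioinformatics
infrastructure groups and anyone auditing the "resourceome" of a literature
corpus.

## What is inside

**Recognition.** A dictionary + rule named-entity recogniser. Candidate
spans (dictionary matches, capitalised tokens, nouns attached to category
keywords) are scored by a fixed inventory of 17 positive and negative
contextual rules — version numbers, URLs, citation markers, category
keywords like *database/software/tool* (positive) or *algorithm/method*
(negative), Hearst patterns ("tools such as X"), head-noun association,
acronym-definition agreement, case/length shape. Scores get a document-wide
adjustment (many weak clues for the same name add up), accepted names are
propagated to their bare occurrences, acronyms whose in-text long form
contradicts the dictionary expansion are rejected, and a threshold tau
produces the final mentions.

**Filtering.** A post-processing classifier re-scores each accepted mention
from its *rule profile only* — 17 binary flags plus the matched-rule count,
deliberately no lexical features — and removes mentions it is at least 80%
confident are false positives. Precision rises, recall drops; the trade is
explicit and auditable (every retained mention keeps its confidence).

**Survey analytics.** Mention- and document-level usage tables per corpus
partition (medicine / biology / bioinformatics via hierarchical journal
subject codes); top-N tables; per-journal mention proportions; relative
usage within the yearly top-100 pool; Year0-normalised trajectories tested
against a Gaussian random-walk envelope whose width grows as sigma·sqrt(t);
the volatility score ΔΣ = Σ_y |x_{y+1} − x_y|; persistence runs (unbroken
yearly usage); long-tail concentration (singleton fraction, top-k shares,
Zipf exponent fitting); cross-corpus name overlap; and a sparse SVD
embedding of the resource × journal count matrix (first singular direction —
scale — dropped, components 2 and 3 plotted).

**Synthetic corpus generator.** Every stage is testable without downloads:
the generator emits JATS-like XML articles with sections, captions, journals
and years, resource usage drawn from a Zipf law, planted growth/decline
trends, ambiguous common-word names, and exact gold standoff annotations.

## Worked example

`python examples/recognize_article.py` parses a small methods section and
prints:

```
6 mentions accepted in article 'demo1':
  'ClustalW'   span=(40, 48)  score=6.80  canonical=ClustalW  rules=[dictionary, version_number, positive_keyword, head_association, case_shape, usage_verb]
  'GenBank'    span=(93, 100)  score=3.30  canonical=GenBank  rules=[dictionary, case_shape, usage_verb]
  'BLAST'      span=(107, 112)  score=3.50  canonical=BLAST  rules=[dictionary, case_shape, usage_verb]
  'Gene Ontology' span=(146, 159)  score=2.00  canonical=Gene Ontology  rules=[dictionary]
  'GO'         span=(161, 163)  score=2.00  canonical=GO  rules=[dictionary, positive_keyword, negative_keyword, acronym_defined, case_shape]
  'R'          span=(210, 211)  score=3.00  canonical=R  rules=[dictionary, usage_verb]
```

Each line is one textual occurrence with its character span, its summed rule
evidence after document-wide adjustment, and the rules that fired — e.g.
`ClustalW` is corroborated by a version number, the head noun *software* and
the usage verb *aligned*, while the bare acronym `GO` is accepted because its
in-text definition "Gene Ontology (GO)" agrees with the dictionary expansion.

`python examples/corpus_survey.py` runs the whole pipeline on 300 generated
articles and prints the survey (output from this build):

```
recognition before filtering: P=0.84 R=0.91 F=0.87 (strict)
after the 0.80-confidence filter: P=1.00 R=0.91 F=0.95 (precision up, recall down)

bioinformatics: 11.1 mentions per document; top resources (fraction of documents): ...
long tail over 235 names: 34% mentioned in a single document; top 5% of names (12) carry 51% of document-level usage
```

The other examples cover temporal trends with the random-walk envelope
(`temporal_trends.py`), the classifier bake-off against a planted
Bayes-optimal AUC (`filter_bakeoff.py`), and journal/resource SVD embedding
(`journal_clustering.py`).

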