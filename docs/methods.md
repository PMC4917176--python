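# Methods

This note documents the models and procedures implemented in `resmine`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Recognition model

Recognition is dictionary- and rule-based, scored per candidate span and
resolved per document.

**Preprocessing.** Tokenisation, sentence splitting, coarse part-of-speech
tagging and head linking are a deterministic shallow parse: closed-class
word lists plus suffix heuristics for tags, and a nearest-head rule that
links every token in a maximal noun-phrase run to the run's last noun, which
in turn links to the sentence root (first verb, else first token). This is a
deliberate trade: full statistical dependency parsing is expensive and
non-deterministic across library versions, while the downstream rules only
consume noun-phrase heads and adjacency. The cost is occasional mis-headed
phrases (adverbs absorbed into noun runs, etc.), which surfaces as rule
noise rather than pipeline failure.

**Candidates** come from three sources: longest-match dictionary n-grams
(case-sensitively confirmed — a short all-caps entry like *GO* or *ON* never
matches an ordinary lowercase word), capitalised tokens away from sentence
starts, and nouns immediately preceding a category keyword. Negative
contexts generate candidates too, so the negative evidence is recorded
instead of silently discarded.

**The 17 rules** (ids fixed, see `resmine.ner.rules.RULE_NAMES`) cover:
dictionary membership (1), version numbers (2), URLs (3), citation markers
(4), positive category keywords in a +/-3-token window (5), negative
keywords (6), Hearst category patterns (7), appositions (8), head-noun
association through the shallow parse (9), restricted head nouns
*program/system/project/service* that only score when corroborated by a
second positive rule (10), acronym-definition agreement (11), case/length
shape rewards and the common-word penalty (12/13), the document-cohort and
propagation flags (14/15, weight 0 — they exist for the filter's feature
space), usage verbs (16), and capitalised out-of-dictionary tokens (17).
Weights and the acceptance threshold tau live in
`resmine/data/default_rules.json`; they were calibrated once against the
synthetic gold corpus and are deliberately coarse (half-point granularity).
With the defaults, a bare dictionary hit on an unambiguous name passes tau,
a bare hit on a common-word name does not, and contextual evidence decides
the rest.

**Document-level stages.** Candidates sharing a normalised surface form a
cohort; each member gains `min(cap, rate * (k-1) * mean positive raw score)`
(defaults: rate 0.35, cap 2.0) — repetition amplifies positive evidence but
never rescues purely negative cohorts, and never lowers a score. Surfaces
whose best member crosses tau are then propagated: bare occurrences not
already candidates are promoted and inherit the seed's adjusted score (the
relative scoring of propagated occurrences is an open design point; score
inheritance keeps document-level acceptance and mention-level recall
consistent). Acronym candidates with a dictionary expansion are screened
against their in-text parenthetical definition (Schwartz–Hearst-style
left-scan over |acronym|+5 tokens); the comparison uses normalised edit
distance with tolerance 0.2, and a contradicting definition rejects every
occurrence in that document. Mentions in captions are recognised in a
separate stream with the same machinery and never share offsets or sections
with body text.

## The rule-profile filter

Each accepted mention is encoded as 17 binary rule flags plus the rule
count — 18 features, no lexical content, so the classifier cannot memorise
surface strings (permuting surfaces provably leaves predictions unchanged).
Models: Bernoulli naive Bayes, random forest (100 trees), linear and RBF
SVMs, and an entropy decision tree, all behind one interface; model
selection uses 10 shuffles of 10-fold stratified cross-validation, with
precision/recall/F1 computed for the false-positive class from pooled fold
confusion counts and AUC from the ranked FP probabilities. Deployment
removes mentions with P(false positive) >= 0.80 — the boundary itself is
removal — and stamps every retained mention with its confidence. Training
labels come from gold alignment; lenient (any-overlap) alignment is the
default since boundary disagreements should not flip a training label.

## Survey analytics

Counting is two-level throughout: *mention-level* (every textual occurrence)
and *document-level* (a resource counts once per document). Corpus
partitions come from hierarchical journal subject codes with prefix
subsumption, which makes bioinformatics a strict subset of biology by
construction; articles whose journal has no catalogue entry stay in the full
corpus only. Reported means and proportions are rounded half-up to one
decimal, matching the convention of printed survey tables.

**Temporal analysis.** Per year, the top-100 resources by document count
form a pool (boundary ties all included); a resource's relative usage is its
count over the pool total, so pool fractions sum to one. Trajectories are
normalised to their first pooled year (Year0 = first appearance, also after
drop-out and re-entry). The significance null is a Gaussian random walk:
bounds at offset t are 1 ± z(0.95)·sigma·sqrt(t). Sigma is a
Gaussian-consistent robust scale (1.4826 × median absolute deviation) of the
pooled year-over-year steps: the pool mixes smooth trajectories of heavy
hitters with violent jumps of resources counted once or twice, and a plain
standard deviation would let that tail noise widen the envelope until no
real trend could ever leave it; on Gaussian steps both estimators coincide,
so the envelope's 95% coverage on a true random walk is preserved. The
volatility score is the sum of absolute differences between consecutive
observed years — the printed summation limits of the source formula would
require a year beyond the data, so the sum runs over observed consecutive
pairs, and single-year series score 0.

**Persistence** selects resources with at least one document mention in
every year from their first to their last observed year, excludes anything
mentioned in the window's start year (those "always existed"), and splits
the remainder by whether they are still mentioned in the final year.

**Long tail.** Singleton fraction and share, top-1/top-10/top-5% shares
(top-5% uses ceil(0.05·n) names), plus a maximum-likelihood Zipf exponent
fit: counts ranked decreasing, a multinomial model with p_r ∝ r^(-s) over
observed ranks, s by bounded scalar minimisation. The MLE is used instead of
a log-log regression because regression slopes are biased by the sparse tail
precisely where these corpora live.

**Clustering.** The resource × journal matrix of document-level counts is
decomposed raw by sparse SVD — no centering, because mean-centering a large
sparse matrix densifies it. The first singular direction orders entities by
total volume ("scale") and is dropped; components 2 and 3 form the
embedding, for journals via the right singular vectors and for resources via
the left. Ten components are computed by default so variance fractions are
meaningful; fractions are over the computed rank. Tiny or rank-deficient
matrices fall back to a dense decomposition, and a vanishing second singular
value flags the projection as degenerate. Tests compare embeddings up to
per-component sign, the only invariance SVD guarantees.

## Evaluation

Strict scoring requires exact offset identity, lenient any character
overlap; both use one-to-one, cardinality-maximal bipartite matching
(greedy-by-overlap ordering only breaks ties), so lenient metrics dominate
strict metrics on every input and the matcher agrees with exhaustive search
on small span sets. Span identity does not require name identity (a
name-aware mode exists, off by default). Undefined precision/recall
(empty denominators) are flagged and reported as 0 rather than raised. AUC
is the rank-based Mann–Whitney statistic with tied ranks averaged.

## The synthetic generator

The generator defines the study conditions for every test. Defaults: 500
articles over 2000–2013, six journals (two bioinformatics, two biology, one
medicine, one uncatalogued) with realistic per-domain mention intensities
(Poisson means 12/10 bioinformatics, 8/7 biology, 3 medicine, 5 general —
bracketing the order-of-magnitude contrast real sub-corpora show), a
300-name dictionary with 10% ambiguous common-word names placed at
middle-to-low ranks, Zipf exponent 1.1, and two planted trends: a rapid
riser (slope +0.8/yr, ~11× over the window — the scale of uptake shown by
resources that went from obscurity to ubiquity) and a slow decliner
(−0.07/yr). Gold mentions are embedded in the contextual frames the rules
target (keyword-adjacent 24%, versioned 15%, usage-verb 18%, bare 15%,
Hearst 10%, URL 8%, negative-keyword 10%), captions carry a 4× bias towards
visualisation-flagged tools, and ambiguous names additionally appear both as
plain prose words and in resource-like "trap" frames, unannotated — the
false-positive diet the filter trains on. Headings use standard variants 85%
of the time and exotic ones otherwise, so the zoner's pattern table is
exercised at realistic, imperfect recall.

What the generator does **not** emulate: real linguistic variety (sentences
are templated), novel out-of-dictionary resource names (recognition recall
against truly unseen names is untested), boundary ambiguity in gold spans
(strict and lenient scores coincide more often than on human annotation),
coreference, multilingual text, and citation structure beyond inline
markers. Passing tests therefore demonstrate the machinery — scoring,
propagation, filtering, counting, trend detection — not performance on real
PubMed Central text.

The labelled-candidate generator for the filter bake-off samples rule
profiles from two discrete mixtures sharing exactly one profile (mass 0.5
under the true-positive class, 0.6 under the false-positive class), which
pins the likelihood-ratio AUC at exactly 1 − (0.5·0.6)/2 = 0.85; the
`bayes_auc` function computes this bound exactly for any pair of mixtures.

## Problem sizes and numerical choices

Tests run the pipeline at 100–2000 articles and the envelope calibration at
1000 replicates; the acceptance script surveys a 1000-article corpus with a
1000-name dictionary (ambiguity 4%) and trains the filter on an independent
300-article corpus. These sizes give stable statistics (recovery of planted
quantities to a few percentage points) while keeping any single run in
seconds. All randomness flows from explicit integer seeds through numpy
Generators; identical seeds reproduce corpora byte for byte. Ties in top-N
tables break lexicographically; mentions straddling a section boundary take
the section of their start offset; empty partitions, single-class training
data, zero-variance step pools and all-zero matrices raise or flag rather
than return silent zeros.

## Known limitations

The rule inventory is a documented reconstruction — the weights are not
fitted to any real corpus, and the shallow parse limits the head-association
rule to local attachments. The dictionary fixture (~290 names) is a small
curated sample, not a compiled registry. Canonical-name merging trusts the
dictionary's variant expansion; names whose variants are not generated
(e.g. idiosyncratic abbreviations) count as separate resources. The
random-walk null assumes independent Gaussian steps with a common scale;
resources with genuinely heteroskedastic usage violate it, and the robust
sigma mitigates but does not remove this.
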