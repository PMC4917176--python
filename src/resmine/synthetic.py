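"""Synthetic corpus generator with gold annotations.

Generates everything the pipeline consumes — a resource dictionary, JATS-like
articles with sections, captions, journals and years, and standoff gold
annotations — with a fully known ground truth, so every stage is testable
without external downloads.

What it emulates: resource usage drawn from a Zipf rank-frequency law with a
configurable exponent; per-journal domain vocabularies; planted linear
growth/decline trends in yearly document frequency; ambiguous resource names
that double as ordinary English words (exercising the false-positive
machinery); mention contexts matching the recogniser's rule frames
(keyword-adjacent, versioned, URL-adjacent, Hearst, usage-verb, bare,
negative-keyword); caption mentions biased towards visualisation tools; and
heading variation that the zoner only partially recognises.

Everything is driven by one numpy Generator: the same seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus_io import Article, CorpusPartition, JournalCatalog, partition_corpus, serialize_article
from .dictionary import Dictionary, DictionaryEntry, make_dictionary
from .ml_filter import FeatureVector, LabeledMention, FP_LABEL, TP_LABEL
from .ner.rules import RULE_IDS

# the pool of ordinary-English resource names; mirrors the recogniser's
# common-word list so ambiguity actually bites
AMBIGUOUS_POOL = [
    "analysis", "cluster", "image", "match", "smart", "cell", "genomes",
    "effective", "spring", "focus", "healthcare", "express", "prism",
    "base", "scan", "trace", "pilot", "mosaic", "compass", "beacon",
    "anchor", "bridge", "canvas", "cascade", "catalyst", "circuit",
    "fusion", "gateway", "harbor", "horizon", "lattice", "medley",
    "nexus", "oracle", "prime", "pulse", "quartz", "relay", "sentinel",
    "spectrum", "summit", "tangent", "vertex", "vortex", "zenith",
]

_SYLLABLES = ["ba", "co", "da", "fe", "gi", "ho", "ja", "ke", "li", "mo",
              "na", "pe", "qui", "ro", "sa", "tu", "ve", "wi", "xo", "zy",
              "lan", "mer", "nex", "plor", "quin", "ser", "tal", "vor"]
_EXPANSION_WORDS = ["Genome", "Sequence", "Protein", "Pathway", "Alignment",
                    "Annotation", "Expression", "Variant", "Structure",
                    "Network", "Marker", "Assembly", "Ontology", "Archive",
                    "Resource", "Database", "Browser", "Explorer", "Atlas",
                    "Registry", "Catalog", "Toolkit", "Workbench", "Portal"]

DOMAINS = ("bioinformatics", "biology", "medicine", "general")


@dataclass(frozen=True)
class JournalProfile:
    name: str
    subject_code: str | None
    domain: str
    mention_mean: float  # Poisson mean of resource mentions per article
    weight: float        # relative article volume


DEFAULT_JOURNALS = (
    JournalProfile("Journal of Computational Genomics", "H01.158.273.180",
                   "bioinformatics", 12.0, 0.18),
    JournalProfile("Briefings in Silico", "H01.158.273.180",
                   "bioinformatics", 10.0, 0.12),
    JournalProfile("Annals of Cell Science", "H01.158.273", "biology", 8.0, 0.20),
    JournalProfile("Molecular Studies Quarterly", "H01.158.273", "biology", 7.0, 0.15),
    JournalProfile("Clinical Practice Today", "H02.403", "medicine", 3.0, 0.20),
    JournalProfile("General Science Reports", None, "general", 5.0, 0.15),
)


@dataclass(frozen=True)
class PlantedTrend:
    """Linear yearly multiplier on a resource's selection weight.

    weight(year) = max(floor, 1 + slope * (year - first_year)).
    """

    rank: int
    slope: float
    floor: float = 0.05


@dataclass
class GeneratorConfig:
    seed: int
    n_articles: int = 500
    years: tuple[int, int] = (2000, 2013)
    journals: tuple[JournalProfile, ...] = DEFAULT_JOURNALS
    dict_size: int = 300
    ambiguity_rate: float = 0.10
    zipf_exponent: float = 1.1
    # a rapid riser (~11x over the 14-year window, the scale of the uptake
    # seen for resources that went from obscurity to ubiquity) and a slow
    # decliner (to ~0.1x, the fate of superseded tools)
    planted_trends: tuple[PlantedTrend, ...] = (
        PlantedTrend(rank=20, slope=0.8),
        PlantedTrend(rank=12, slope=-0.07),
    )
    # mixture over mention context frames (gold mentions)
    frame_mix: dict = field(default_factory=lambda: {
        "keyword": 0.24, "versioned": 0.15, "url": 0.08, "hearst": 0.10,
        "usage": 0.18, "bare": 0.15, "negative": 0.10,
    })
    # ambiguous names as ordinary prose words (never gold)
    plain_word_mean: float = 1.0
    # ambiguous names dropped into resource-like frames (never gold: the
    # classic false-positive generator)
    trap_mean: float = 0.7
    caption_prob: float = 0.6
    caption_mention_mean: float = 1.0
    viz_fraction: float = 0.15   # resources flagged as visualisation tools
    viz_caption_boost: float = 4.0
    domain_boost: float = 2.0
    heading_standard_prob: float = 0.85
    section_mix: dict = field(default_factory=lambda: {
        "introduction": 0.15, "methods": 0.55,
        "results_discussion": 0.25, "conclusion": 0.05,
    })

    def __post_init__(self) -> None:
        for r in (self.ambiguity_rate, self.caption_prob, self.viz_fraction,
                  self.heading_standard_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    start: int
    end: int
    name: str          # canonical resource name
    surface: str
    stream: str = "body"
    caption_index: int | None = None
    section: str | None = None  # true rhetorical section at generation time

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# dictionary generation


def generate_dictionary(n: int, ambiguity_rate: float = 0.1,
                        seed: int = 0) -> tuple[Dictionary, pd.DataFrame]:
    """Generate n dictionary entries plus a hidden truth table.

    Exactly round(n * ambiguity_rate) entries are ordinary English words.
    Acronym-shaped entries carry an expected expansion.  The truth table
    records rank, domain, ambiguity and visualisation flags.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_amb = int(round(n * ambiguity_rate))
    if n_amb > len(AMBIGUOUS_POOL):
        raise ValueError(f"ambiguity_rate too high: need {n_amb} common words, "
                         f"pool has {len(AMBIGUOUS_POOL)}")
    amb_names = list(rng.choice(AMBIGUOUS_POOL, size=n_amb, replace=False))
    # ambiguous names take middle/low ranks: common-word resources are real
    # but rarely dominant
    amb_ranks = set()
    if n_amb:
        lo = min(30, n - n_amb)
        amb_ranks = set(int(r) for r in
                        rng.choice(np.arange(lo, n), size=n_amb, replace=False))

    entries = []
    rows = []
    used_names: set[str] = set(amb_names)
    amb_iter = iter(amb_names)
    for rank in range(1, n + 1):
        ambiguous = (rank - 1) in amb_ranks
        expansion = None
        if ambiguous:
            name = next(amb_iter)
            rtype = "SW"
        else:
            shape = rng.choice(["acronym", "camel", "plain"], p=[0.35, 0.45, 0.20])
            while True:
                if shape == "acronym":
                    k = int(rng.integers(2, 5))
                    words = list(rng.choice(_EXPANSION_WORDS, size=k, replace=False))
                    expansion = " ".join(words)
                    name = "".join(w[0] for w in words).upper()
                elif shape == "camel":
                    parts = [str(rng.choice(_SYLLABLES)).capitalize()
                             for _ in range(int(rng.integers(2, 4)))]
                    name = "".join(parts)
                else:
                    name = "".join(rng.choice(_SYLLABLES, size=int(rng.integers(2, 4))))
                    name = name.capitalize()
                if name not in used_names:
                    break
                expansion = None
            used_names.add(name)
            rtype = str(rng.choice(["DB", "SW", "PK", "ONT"], p=[0.3, 0.4, 0.2, 0.1]))
        domain = str(rng.choice(DOMAINS, p=[0.40, 0.30, 0.15, 0.15]))
        viz = bool(rng.random() < 0.15) and rtype == "SW"
        entries.append(DictionaryEntry(canonical=name, rtype=rtype,
                                       source="synthetic",
                                       expected_expansion=expansion))
        rows.append({"rank": rank, "canonical": name, "rtype": rtype,
                     "domain": domain, "ambiguous": ambiguous, "viz": viz,
                     "expansion": expansion})
    truth = pd.DataFrame(rows)
    return make_dictionary(entries), truth


# ---------------------------------------------------------------------------
# article text assembly

_FILLER = [
    "The samples were collected from twelve donors over a period of three months.",
    "All measurements were repeated in triplicate to reduce technical variation.",
    "Previous studies have reported conflicting findings on this topic.",
    "The observed differences were consistent across replicates.",
    "Statistical significance was assessed at the five percent level.",
    "These findings are in line with earlier reports from independent groups.",
    "Participants provided written informed consent before enrolment.",
    "The remaining discrepancies are likely due to batch effects.",
    "Quality control excluded samples with low yield.",
    "Further work is needed to confirm these observations in larger cohorts.",
    "The distribution of values was approximately symmetric.",
    "No adverse events were recorded during the study period.",
]

_PLAIN_WORD_TEMPLATES = [
    "This {w} provided additional insight into the data.",
    "A careful {w} of the raw values revealed no outliers.",
    "Each {w} was inspected manually for consistency.",
    "The {w} stage took several hours to complete.",
]

_HEADINGS = {
    "introduction": (["Introduction", "Background"],
                     ["Overview of the study", "Context and aims"]),
    "methods": (["Methods", "Materials and Methods", "Experimental procedures"],
                ["Computational workflow", "Data preparation"]),
    "results_discussion": (["Results", "Results and Discussion", "Discussion"],
                           ["Principal observations", "Outcomes"]),
    "conclusion": (["Conclusions", "Concluding remarks"],
                   ["Final notes", "Closing statement"]),
}

_SECTION_ORDER = ("introduction", "methods", "results_discussion", "conclusion")

_KW_BY_TYPE = {"DB": "database", "SW": "software", "PK": "package",
               "ONT": "ontology", "unknown": "tool"}


def _frame_sentence(frame: str, name: str, rtype: str, rng) -> tuple[str, int]:
    """Build one sentence embedding ``name``; returns (text, name offset)."""
    kw = _KW_BY_TYPE.get(rtype, "tool")
    if frame == "keyword":
        templates = [
            ("We stored the intermediate results in the {name} " + kw + ".", None),
            ("The {name} " + kw + " was central to the workflow.", None),
            ("Annotations were taken from the {name} " + kw + ".", None),
        ]
    elif frame == "versioned":
        maj, mnr = int(rng.integers(1, 9)), int(rng.integers(0, 9))
        templates = [
            ("Alignments were generated with {name} (version " + f"{maj}.{mnr}" + ").", None),
            ("We ran {name} " + f"{maj}.{mnr}" + " with default parameters.", None),
        ]
    elif frame == "url":
        slug = "".join(rng.choice(list("abcdefghij"), size=5))
        templates = [
            ("Data were downloaded from {name} (http://" + slug + ".example.org).", None),
            ("The {name} " + kw + " is available at http://" + slug + ".example.org.", None),
        ]
    elif frame == "hearst":
        plural = {"database": "databases", "software": "tools",
                  "package": "packages", "ontology": "ontologies",
                  "tool": "tools"}.get(kw, "tools")
        templates = [
            ("We relied on " + plural + " such as {name} for downstream processing.", None),
            ("Established " + plural + " including {name} were considered.", None),
        ]
    elif frame == "usage":
        templates = [
            ("Sequences were aligned using {name}.", None),
            ("All records were processed with {name} before filtering.", None),
            ("Figures were generated using {name}.", None),
        ]
    elif frame == "bare":
        templates = [
            ("Results from {name} were consistent with previous reports.", None),
            ("The output of {name} required no further curation.", None),
        ]
    elif frame == "negative":
        templates = [
            ("The {name} algorithm was modified for this study.", None),
            ("Our {name} approach differs from earlier methods.", None),
        ]
    else:
        raise ValueError(f"unknown frame {frame!r}")
    template = templates[int(rng.integers(len(templates)))][0]
    offset = template.index("{name}")
    return template.replace("{name}", name), offset


_CAPTION_TEMPLATES = [
    ("Figure {i}. Heatmap of normalised counts generated with {name}.", True),
    ("Figure {i}. Visualisation of the network produced in {name}.", True),
    ("Table {i}. Summary statistics per sample group.", False),
    ("Figure {i}. Distribution of quality scores across batches.", False),
]


class _BodyBuilder:
    """Accumulates newline-separated blocks while tracking offsets."""

    def __init__(self) -> None:
        self.blocks: list[str] = []
        self.heading_spans: list[tuple[str, int, int]] = []
        self._pos = 0

    def _advance(self, text: str) -> int:
        start = self._pos + (1 if self.blocks else 0)
        self._pos = start + len(text)
        self.blocks.append(text)
        return start

    def add_heading(self, text: str) -> None:
        start = self._advance(text)
        self.heading_spans.append((text, start, start + len(text)))

    def add_paragraph(self, sentences: list[tuple[str, list[tuple[int, str, str]]]]
                      ) -> list[tuple[int, str, str]]:
        """sentences: (text, [(offset_in_sentence, surface, canonical), ...]).

        Returns the mention records with absolute body offsets.
        """
        text = " ".join(s for s, _ in sentences)
        start = self._advance(text)
        out = []
        cursor = 0
        for s, anns in sentences:
            for off, surface, canonical in anns:
                abs_off = start + cursor + off
                out.append((abs_off, surface, canonical))
            cursor += len(s) + 1
        return out

    def body(self) -> str:
        return "\n".join(self.blocks)


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    articles: list[Article]
    gold: list[GoldAnnotation]
    dictionary: Dictionary
    dict_truth: pd.DataFrame
    catalog: JournalCatalog
    doc_meta: dict[str, tuple[str, int]]
    section_truth: dict[str, list[tuple[str, str]]]  # doc -> (heading, label)

    def partitions(self) -> list[CorpusPartition]:
        return partition_corpus(self.articles, self.catalog)

    def gold_mentions(self):
        """Gold annotations shaped like recogniser mentions, for aggregation."""
        return [_GoldAsMention(g) for g in self.gold]

    def gold_body_spans(self) -> dict[str, list[tuple[int, int]]]:
        spans: dict[str, list[tuple[int, int]]] = {a.doc_id: [] for a in self.articles}
        for g in self.gold:
            if g.stream == "body":
                spans[g.doc_id].append(g.span)
        return spans

    def truth_usage(self):
        """Usage table recounted directly from the gold annotations."""
        from .analytics import aggregate_usage
        return aggregate_usage(self.gold_mentions(), self.partitions(), self.doc_meta)

    def xml(self) -> dict[str, str]:
        return {a.doc_id: serialize_article(a) for a in self.articles}


class _GoldAsMention:
    __slots__ = ("doc_id", "span", "surface", "canonical", "stream", "section")

    def __init__(self, g: GoldAnnotation):
        self.doc_id = g.doc_id
        self.span = g.span
        self.surface = g.surface
        self.canonical = g.name
        self.stream = g.stream
        self.section = g.section


def _trend_multiplier(config: GeneratorConfig, rank: int, year: int) -> float:
    for t in config.planted_trends:
        if t.rank == rank:
            return max(t.floor, 1.0 + t.slope * (year - config.years[0]))
    return 1.0


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate the full corpus: articles, gold annotations, truth tables."""
    rng = np.random.default_rng(config.seed)
    dictionary, dict_truth = generate_dictionary(
        config.dict_size, config.ambiguity_rate,
        seed=int(rng.integers(2 ** 31)))
    n = config.dict_size
    ranks = np.arange(1, n + 1, dtype=float)
    base_w = ranks ** (-config.zipf_exponent)
    domains = dict_truth["domain"].to_numpy()
    viz = dict_truth["viz"].to_numpy()
    names = dict_truth["canonical"].to_numpy()
    rtypes = dict_truth["rtype"].to_numpy()
    ambiguous_names = list(dict_truth.loc[dict_truth["ambiguous"], "canonical"])

    catalog = JournalCatalog(codes={
        j.name: {j.subject_code} for j in config.journals if j.subject_code})
    j_weights = np.array([j.weight for j in config.journals], dtype=float)
    j_weights = j_weights / j_weights.sum()

    frame_names = list(config.frame_mix)
    frame_probs = np.array([config.frame_mix[f] for f in frame_names], dtype=float)
    frame_probs = frame_probs / frame_probs.sum()
    sec_names = list(config.section_mix)
    sec_probs = np.array([config.section_mix[s] for s in sec_names], dtype=float)
    sec_probs = sec_probs / sec_probs.sum()

    y0, y1 = config.years
    articles: list[Article] = []
    gold: list[GoldAnnotation] = []
    doc_meta: dict[str, tuple[str, int]] = {}
    section_truth: dict[str, list[tuple[str, str]]] = {}

    # per-year selection weights (trend-modulated), cached
    year_weights: dict[tuple[int, str], np.ndarray] = {}

    def weights_for(year: int, jdomain: str) -> np.ndarray:
        key = (year, jdomain)
        if key not in year_weights:
            w = base_w.copy()
            for t in config.planted_trends:
                w[t.rank - 1] *= max(t.floor, 1.0 + t.slope * (year - y0))
            boost = np.where(domains == jdomain, config.domain_boost, 1.0)
            if jdomain == "general":
                boost = np.ones_like(boost)
            w = w * boost
            year_weights[key] = w / w.sum()
        return year_weights[key]

    for i in range(config.n_articles):
        doc_id = f"S{i:05d}"
        jp = config.journals[int(rng.choice(len(config.journals), p=j_weights))]
        year = int(rng.integers(y0, y1 + 1))
        doc_meta[doc_id] = (jp.name, year)

        n_mentions = int(rng.poisson(jp.mention_mean))
        probs = weights_for(year, jp.domain)
        picked = rng.choice(n, size=n_mentions, p=probs) if n_mentions else np.array([], dtype=int)

        # distribute mention occurrences over sections
        per_section: dict[str, list[int]] = {s: [] for s in _SECTION_ORDER}
        for ridx in picked:
            sec = sec_names[int(rng.choice(len(sec_names), p=sec_probs))]
            per_section[sec].append(int(ridx))

        n_plain = int(rng.poisson(config.plain_word_mean)) if ambiguous_names else 0
        n_trap = int(rng.poisson(config.trap_mean)) if ambiguous_names else 0

        builder = _BodyBuilder()
        truth_headings: list[tuple[str, str]] = []
        mention_records: list[tuple[int, str, str, str]] = []  # off, surf, canon, sec

        for sec in _SECTION_ORDER:
            std, exotic = _HEADINGS[sec]
            if rng.random() < config.heading_standard_prob:
                heading = std[int(rng.integers(len(std)))]
            else:
                heading = exotic[int(rng.integers(len(exotic)))]
            builder.add_heading(heading)
            truth_headings.append((heading, sec))

            sentences: list[tuple[str, list[tuple[int, str, str]]]] = []
            n_filler = int(rng.integers(2, 5))
            for _ in range(n_filler):
                sentences.append((_FILLER[int(rng.integers(len(_FILLER)))], []))
            for ridx in per_section[sec]:
                frame = frame_names[int(rng.choice(len(frame_names), p=frame_probs))]
                text, off = _frame_sentence(frame, str(names[ridx]),
                                            str(rtypes[ridx]), rng)
                sentences.append((text, [(off, str(names[ridx]), str(names[ridx]))]))
            if sec == "methods":
                for _ in range(n_trap):
                    word = ambiguous_names[int(rng.integers(len(ambiguous_names)))]
                    frame = "keyword" if rng.random() < 0.7 else "hearst"
                    text, _off = _frame_sentence(frame, word, "SW", rng)
                    sentences.append((text, []))  # deliberately unannotated
            if sec in ("introduction", "results_discussion"):
                for _ in range(n_plain):
                    word = ambiguous_names[int(rng.integers(len(ambiguous_names)))]
                    tmpl = _PLAIN_WORD_TEMPLATES[int(rng.integers(len(_PLAIN_WORD_TEMPLATES)))]
                    sentences.append((tmpl.replace("{w}", word), []))
                n_plain = 0  # only once
            order = rng.permutation(len(sentences))
            sentences = [sentences[k] for k in order]
            for off, surface, canonical in builder.add_paragraph(sentences):
                mention_records.append((off, surface, canonical, sec))

        captions: list[str] = []
        caption_gold: list[tuple[int, int, str, str]] = []  # cap_idx, off, surf, canon
        if rng.random() < config.caption_prob:
            n_caps = int(rng.integers(1, 3))
            cap_w = probs * np.where(viz, config.viz_caption_boost, 1.0)
            cap_w = cap_w / cap_w.sum()
            for ci in range(n_caps):
                tmpl, has_mention = _CAPTION_TEMPLATES[int(rng.integers(len(_CAPTION_TEMPLATES)))]
                text = tmpl.replace("{i}", str(ci + 1))
                if has_mention and rng.poisson(config.caption_mention_mean) > 0:
                    ridx = int(rng.choice(n, p=cap_w))
                    off = text.index("{name}")
                    text = text.replace("{name}", str(names[ridx]))
                    caption_gold.append((ci, off, str(names[ridx]), str(names[ridx])))
                else:
                    text = text.replace("{name}", "standard plotting scripts")
                captions.append(text)

        article = Article(doc_id=doc_id, journal=jp.name, year=year,
                          title=f"Synthetic article {doc_id}",
                          body=builder.body(), captions=captions,
                          heading_spans=builder.heading_spans)
        article.validate()
        articles.append(article)
        section_truth[doc_id] = truth_headings
        for off, surface, canonical, sec in mention_records:
            assert article.body[off:off + len(surface)] == surface
            gold.append(GoldAnnotation(doc_id=doc_id, start=off,
                                       end=off + len(surface), name=canonical,
                                       surface=surface, stream="body",
                                       section=sec))
        for ci, off, surface, canonical in caption_gold:
            assert captions[ci][off:off + len(surface)] == surface
            gold.append(GoldAnnotation(doc_id=doc_id, start=off,
                                       end=off + len(surface), name=canonical,
                                       surface=surface, stream="caption",
                                       caption_index=ci, section="caption"))

    return SyntheticCorpus(config=config, articles=articles, gold=gold,
                           dictionary=dictionary, dict_truth=dict_truth,
                           catalog=catalog, doc_meta=doc_meta,
                           section_truth=section_truth)


# ---------------------------------------------------------------------------
# labelled rule-profile candidates for the filter bake-off


#: class-conditional distributions over matched-rule profiles.  The single
#: shared profile {dictionary} carries mass 0.5 under TP and 0.6 under FP,
#: which pins the Bayes-optimal AUC at exactly 1 - (0.5*0.6)/2 = 0.85.
DEFAULT_TP_PROFILES: dict[frozenset, float] = {
    frozenset({1}): 0.50,
    frozenset({1, 5, 9}): 0.16,
    frozenset({1, 2, 16}): 0.14,
    frozenset({1, 16}): 0.10,
    frozenset({1, 7, 5}): 0.06,
    frozenset({1, 3, 16}): 0.04,
}
DEFAULT_FP_PROFILES: dict[frozenset, float] = {
    frozenset({1}): 0.60,
    frozenset({1, 13}): 0.16,
    frozenset({1, 5, 13, 9}): 0.08,
    frozenset({6}): 0.06,
    frozenset({17}): 0.06,
    frozenset({1, 6}): 0.04,
}


def bayes_auc(tp_profiles: dict[frozenset, float],
              fp_profiles: dict[frozenset, float]) -> float:
    """Exact AUC of the likelihood-ratio ranking for two discrete mixtures."""
    profiles = set(tp_profiles) | set(fp_profiles)
    lr = {p: (tp_profiles.get(p, 0.0), fp_profiles.get(p, 0.0)) for p in profiles}

    def ratio(p):
        tp, fp = lr[p]
        return math.inf if fp == 0 else tp / fp

    auc = 0.0
    for a in profiles:      # drawn from FP
        for b in profiles:  # drawn from TP
            pa = lr[a][1]
            pb = lr[b][0]
            if pa == 0 or pb == 0:
                continue
            ra, rb = ratio(a), ratio(b)
            if rb > ra:
                auc += pa * pb
            elif rb == ra:
                auc += 0.5 * pa * pb
    return auc


def generate_labeled_candidates(
        n: int = 1000, fp_fraction: float = 0.5, seed: int = 0,
        tp_profiles: dict[frozenset, float] | None = None,
        fp_profiles: dict[frozenset, float] | None = None) -> list[LabeledMention]:
    """Sample labelled rule-profile feature vectors from the two mixtures."""
    tp_profiles = DEFAULT_TP_PROFILES if tp_profiles is None else tp_profiles
    fp_profiles = DEFAULT_FP_PROFILES if fp_profiles is None else fp_profiles
    rng = np.random.default_rng(seed)
    out = []
    for dist, label, count in (
            (tp_profiles, TP_LABEL, n - int(round(n * fp_fraction))),
            (fp_profiles, FP_LABEL, int(round(n * fp_fraction)))):
        keys = sorted(dist, key=lambda p: tuple(sorted(p)))
        probs = np.array([dist[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        for idx in rng.choice(len(keys), size=count, p=probs):
            rule_ids = keys[int(idx)]
            flags = tuple(1 if rid in rule_ids else 0 for rid in RULE_IDS)
            out.append(LabeledMention(
                features=FeatureVector(rule_flags=flags, rule_count=sum(flags)),
                label=label))
    order = rng.permutation(len(out))
    return [out[int(k)] for k in order]
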