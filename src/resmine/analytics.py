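"""Corpus usage statistics.

Everything downstream of recognition: mention/document-level aggregation into
a usage table, top-N reports, per-journal proportions, temporal relative
usage within the yearly top-100 pool, Year0 normalisation with Gaussian
random-walk significance bounds, the volatility score (sum of absolute
year-over-year changes in relative usage), persistence runs, long-tail
shares, Zipf-exponent fitting, and cross-corpus name overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import median_abs_deviation, norm

from ._util import round_half_up
from .corpus_io import MISSING_YEAR, CorpusPartition

logger = logging.getLogger(__name__)


@dataclass
class UsageTable:
    """Counts per (resource, partition, year, journal) at two levels.

    ``mention_count`` sums textual occurrences, ``doc_count`` counts distinct
    documents with at least one occurrence.  Rows with year == MISSING_YEAR
    hold mentions whose article year was unknown: they are excluded from
    temporal queries but participate in all-years totals.
    """

    df: pd.DataFrame
    n_docs: dict[str, int] = field(default_factory=dict)              # partition -> docs
    n_docs_by_year: dict[tuple[str, int], int] = field(default_factory=dict)
    n_docs_by_journal: dict[str, int] = field(default_factory=dict)   # journal -> docs

    def partition_df(self, partition: str) -> pd.DataFrame:
        if partition not in self.n_docs:
            raise KeyError(f"unknown partition {partition!r}")
        return self.df[self.df["partition"] == partition]


def _level_col(level: str) -> str:
    if level in ("mention", "mentions"):
        return "mention_count"
    if level in ("document", "doc", "documents"):
        return "doc_count"
    raise ValueError(f"unknown counting level {level!r}")


def aggregate_usage(mentions, partitions: Sequence[CorpusPartition],
                    doc_meta: Mapping[str, tuple[str, int]]) -> UsageTable:
    """Build the usage table from a mention stream.

    ``mentions`` need doc_id plus a canonical name (falling back to the
    surface form); ``doc_meta`` maps doc_id -> (journal, year).  Mentions in
    documents with a missing year are logged and placed in MISSING_YEAR
    rows.  Document-level counts count distinct documents per cell.
    """
    rows = []
    for m in mentions:
        journal, year = doc_meta[m.doc_id]
        if year < 1900:
            year = MISSING_YEAR
        rows.append((m.doc_id, m.canonical or m.surface, journal, year))
    base = pd.DataFrame(rows, columns=["doc_id", "resource", "journal", "year"])
    n_missing = int((base["year"] == MISSING_YEAR).sum()) if len(base) else 0
    if n_missing:
        logger.warning("%d mentions lack a publication year; kept only in "
                       "all-years cells", n_missing)

    parts = {p.name: p for p in partitions}
    tables = []
    doc_totals: dict[str, pd.Series] = {}
    for name, p in parts.items():
        sub = base[base["doc_id"].isin(p.doc_ids)] if len(base) else base
        if len(sub) == 0:
            continue
        cell = sub.groupby(["resource", "year", "journal"]).agg(
            mention_count=("doc_id", "size"),
            doc_count=("doc_id", "nunique"),
        ).reset_index()
        cell.insert(1, "partition", name)
        tables.append(cell)
        doc_totals[name] = sub.drop_duplicates(["resource", "doc_id"]) \
                              .groupby("resource").size()
    if tables:
        df = pd.concat(tables, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["resource", "partition", "year", "journal",
                                   "mention_count", "doc_count"])

    n_docs = {p.name: len(p.doc_ids) for p in partitions}
    n_docs_by_year: dict[tuple[str, int], int] = {}
    n_docs_by_journal: dict[str, int] = {}
    for p in partitions:
        for doc_id in p.doc_ids:
            journal, year = doc_meta[doc_id]
            if year >= 1900:
                key = (p.name, year)
                n_docs_by_year[key] = n_docs_by_year.get(key, 0) + 1
            if p.name == "full":
                n_docs_by_journal[journal] = n_docs_by_journal.get(journal, 0) + 1
    table = UsageTable(df=df, n_docs=n_docs, n_docs_by_year=n_docs_by_year,
                       n_docs_by_journal=n_docs_by_journal)
    table._doc_totals = doc_totals  # distinct-doc totals per resource/partition
    return table


def _resource_doc_totals(u: UsageTable, partition: str) -> pd.Series:
    totals = getattr(u, "_doc_totals", {})
    if partition in totals:
        return totals[partition]
    # fall back: upper bound by summing cells (exact when each doc has one
    # journal/year, which holds for any corpus built here)
    return u.partition_df(partition).groupby("resource")["doc_count"].sum()


def mean_mentions_per_document(total_mentions: int, n_docs: int) -> float:
    """Mean mentions per document, reported half-up at 1 decimal."""
    if n_docs <= 0:
        raise ValueError("n_docs must be positive")
    return round_half_up(total_mentions / n_docs, 1)


def top_resources(u: UsageTable, partition: str, level: str = "document",
                  n: int = 10) -> list[tuple[str, float]]:
    """Top-N resources in a partition.

    mention level: mean mentions per document of the partition; document
    level: fraction of the partition's documents containing the resource.
    Ties are broken lexicographically.
    """
    n_docs = u.n_docs.get(partition)
    if n_docs is None:
        raise KeyError(f"unknown partition {partition!r}")
    col = _level_col(level)
    if col == "doc_count":
        totals = _resource_doc_totals(u, partition)
    else:
        totals = u.partition_df(partition).groupby("resource")[col].sum()
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return [(name, cnt / n_docs) for name, cnt in ranked]


def journal_proportions(u: UsageTable, min_articles: int = 1000,
                        level: str = "mention") -> pd.DataFrame:
    """Journals ranked by mentions-per-article proportion.

    Journals with fewer than ``min_articles`` articles are excluded.
    Proportion = counts / articles, half-up at 1 decimal.  Counts come from
    the full partition at the requested level.
    """
    col = _level_col(level)
    sub = u.partition_df("full")
    counts = sub.groupby("journal")[col].sum()
    rows = []
    for journal, n_articles in u.n_docs_by_journal.items():
        if n_articles < min_articles:
            continue
        c = int(counts.get(journal, 0))
        rows.append({"journal": journal, "articles": n_articles, "mentions": c,
                     "proportion": round_half_up(c / n_articles, 1)})
    df = pd.DataFrame(rows, columns=["journal", "articles", "mentions", "proportion"])
    return df.sort_values(["proportion", "journal"], ascending=[False, True],
                          ignore_index=True)


# ---------------------------------------------------------------------------
# temporal analysis


@dataclass
class UsageSeries:
    """Relative frequency of one resource within the yearly top-pool."""

    resource: str
    x: dict[int, float] = field(default_factory=dict)

    def years(self) -> list[int]:
        return sorted(self.x)

    def values(self) -> list[float]:
        return [self.x[y] for y in self.years()]


def relative_usage_series(u: UsageTable, partition: str, years: Sequence[int],
                          pool: int = 100) -> dict[str, UsageSeries]:
    """Per-year relative usage within the top-``pool`` resources.

    Per year, resources are ranked by document-level count; the top ``pool``
    (ties at the boundary all included) form the pool, and each member's
    value is its count divided by the pool total — the pool fractions sum to
    one each year.
    """
    if list(years) != sorted(set(years)) or (
            len(years) > 1 and years[-1] - years[0] != len(years) - 1):
        raise ValueError("years must be contiguous and increasing")
    sub = u.partition_df(partition)
    series: dict[str, UsageSeries] = {}
    for year in years:
        ydf = sub[sub["year"] == year]
        counts = ydf.groupby("resource")["doc_count"].sum().sort_values(ascending=False)
        if len(counts) == 0:
            continue
        if len(counts) <= pool:
            if len(counts) < pool:
                logger.info("%s %d: only %d resources; pool shrinks", partition,
                            year, len(counts))
            pool_counts = counts
        else:
            cutoff = counts.iloc[pool - 1]
            pool_counts = counts[counts >= cutoff]  # boundary ties included
        total = pool_counts.sum()
        for resource, cnt in pool_counts.items():
            series.setdefault(resource, UsageSeries(resource=resource)).x[year] = cnt / total
    return series


def normalize_to_year0(s: UsageSeries) -> UsageSeries:
    """Divide every value by the value at the first observed year."""
    years = s.years()
    if not years:
        raise ValueError("empty series")
    base = s.x[years[0]]
    return UsageSeries(resource=s.resource, x={y: s.x[y] / base for y in years})


@dataclass
class RandomWalkEnvelope:
    sigma: float
    z: float
    horizon: int
    degenerate: bool = False

    def bounds(self, t: int) -> tuple[float, float]:
        """(lower, upper) bound at offset t from Year0; width grows as sqrt(t)."""
        if t < 0:
            raise ValueError("offset must be >= 0")
        half = self.z * self.sigma * math.sqrt(t)
        return (1.0 - half, 1.0 + half)

    def as_table(self) -> list[tuple[int, float, float]]:
        return [(t, *self.bounds(t)) for t in range(self.horizon + 1)]


def random_walk_bounds(all_series: Iterable[UsageSeries],
                       confidence: float = 0.95,
                       horizon: int = 13) -> RandomWalkEnvelope:
    """Gaussian random-walk null envelope for Year0-normalised trajectories.

    The step spread sigma is a Gaussian-consistent robust scale estimate
    (1.4826 x the median absolute deviation) of the pooled normalised
    year-over-year changes across all series; the envelope at offset t is
    1 +/- z(confidence) * sigma * sqrt(t).  The robust estimator matters:
    the pool mixes well-observed trajectories with heavy-tailed steps from
    sparsely counted resources, which would inflate a plain standard
    deviation; on Gaussian steps both estimators agree.  A trajectory
    leaving the envelope diverges from the no-trend null at the given
    confidence.
    """
    steps: list[float] = []
    for s in all_series:
        ns = normalize_to_year0(s)
        years = ns.years()
        for a, b in zip(years, years[1:]):
            if b - a == 1:  # only true year-over-year steps
                steps.append(ns.x[b] - ns.x[a])
    if len(steps) < 2:
        raise ValueError("need at least two pooled year-over-year steps")
    sigma = float(median_abs_deviation(steps, scale="normal"))
    z = float(norm.ppf(0.5 + confidence / 2))
    degenerate = sigma == 0.0
    if degenerate:
        logger.warning("zero pooled variance; envelope degenerates to the baseline")
    return RandomWalkEnvelope(sigma=sigma, z=z, horizon=horizon, degenerate=degenerate)


def delta_sigma(s: UsageSeries) -> float:
    """Volatility: sum of |x_{y+1} - x_y| over consecutive observed years.

    Resources seen in a single year have an empty sum (0.0); plots elsewhere
    filter those out, the function itself does not.
    """
    years = s.years()
    return float(sum(abs(s.x[b] - s.x[a]) for a, b in zip(years, years[1:])))


@dataclass(frozen=True)
class PersistenceRecord:
    resource: str
    first_year: int
    last_year: int
    unbroken: bool
    current: bool


def persistence_set(u: UsageTable, partition: str, start_year: int = 2000,
                    end_year: int | None = None) -> list[PersistenceRecord]:
    """Resources with an unbroken yearly run of document mentions.

    A resource qualifies if it has >= 1 document mention in every year from
    its first observed year through its last, with no gaps.  Resources with
    any mention in ``start_year`` are excluded (they 'always existed' and
    belong to the top, not medium, usage class).  ``current`` marks mentions
    in ``end_year`` (default: the latest year in the table).
    """
    sub = u.partition_df(partition)
    sub = sub[sub["year"] != MISSING_YEAR]
    if end_year is None:
        end_year = int(sub["year"].max()) if len(sub) else start_year
    out = []
    for resource, grp in sub.groupby("resource"):
        years = set(int(y) for y in grp.loc[grp["doc_count"] > 0, "year"])
        years = {y for y in years if y >= start_year}
        if not years or start_year in years:
            continue
        first, last = min(years), max(years)
        if set(range(first, last + 1)) - years:
            continue  # gap: excluded
        out.append(PersistenceRecord(resource=resource, first_year=first,
                                     last_year=last, unbroken=True,
                                     current=(last == end_year)))
    return sorted(out, key=lambda r: (r.first_year, r.resource))


# ---------------------------------------------------------------------------
# long tail


@dataclass(frozen=True)
class LongTailSummary:
    n_resources: int
    singleton_fraction: float
    singleton_mention_share: float
    top_1_share: float
    top_10_share: float
    top_5pct_share: float
    top_5pct_names: int


def long_tail_summary(u: UsageTable, partition: str,
                      level: str = "document") -> LongTailSummary:
    """Concentration-of-usage summary for one partition.

    singleton_fraction: share of names with count exactly 1;
    singleton_mention_share: their share of total counts; top-k shares use
    k = 1, 10 and ceil(5% of names).
    """
    if level in ("document", "doc", "documents"):
        totals = _resource_doc_totals(u, partition)
    else:
        totals = u.partition_df(partition).groupby("resource")["mention_count"].sum()
    counts = np.sort(totals.to_numpy())[::-1]
    if counts.size == 0:
        raise ValueError(f"partition {partition!r} has no usage")
    n = int(counts.size)
    total = float(counts.sum())
    singletons = int((counts == 1).sum())
    k5 = max(1, math.ceil(0.05 * n))
    return LongTailSummary(
        n_resources=n,
        singleton_fraction=singletons / n,
        singleton_mention_share=singletons / total,
        top_1_share=float(counts[:1].sum()) / total,
        top_10_share=float(counts[:10].sum()) / total,
        top_5pct_share=float(counts[:k5].sum()) / total,
        top_5pct_names=k5,
    )


def fit_zipf_exponent(counts: Sequence[int]) -> float:
    """Maximum-likelihood Zipf exponent for rank-frequency counts.

    Counts are ranked in decreasing order; the model is a multinomial with
    p_r proportional to r^(-s) over the observed ranks, and s maximises the
    multinomial log-likelihood.
    """
    c = np.sort(np.asarray(counts, dtype=float))[::-1]
    c = c[c > 0]
    if c.size < 2:
        raise ValueError("need at least two ranks to fit an exponent")
    ranks = np.arange(1, c.size + 1, dtype=float)
    log_r = np.log(ranks)
    n = c.sum()

    def neg_ll(s: float) -> float:
        return s * float((c * log_r).sum()) + n * math.log(float(np.exp(-s * log_r).sum()))

    res = minimize_scalar(neg_ll, bounds=(0.05, 4.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# name overlap


def name_overlap(u: UsageTable, partition_names: Sequence[str]) -> dict[str, dict[str, float]]:
    """Per-partition breakdown of unique-name sharing.

    For each listed partition, the fraction of its unique resource names that
    appear only there ('unique'), plus the fraction shared with each
    combination of the other listed partitions (keys like 'biology' or
    'biology+medicine').
    """
    if len(partition_names) < 2:
        raise ValueError("need at least two partitions to compare")
    vocab = {p: set(u.partition_df(p)["resource"].unique()) for p in partition_names}
    out: dict[str, dict[str, float]] = {}
    for p in partition_names:
        names = vocab[p]
        breakdown: dict[str, int] = {}
        for name in names:
            others = sorted(q for q in partition_names if q != p and name in vocab[q])
            key = "+".join(others) if others else "unique"
            breakdown[key] = breakdown.get(key, 0) + 1
        total = len(names)
        out[p] = {k: v / total for k, v in sorted(breakdown.items())} if total else {}
    return out
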