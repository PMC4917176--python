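"""Usage aggregation and the survey statistics."""

import math

import numpy as np
import pytest

from resmine.analytics import (
    UsageSeries,
    aggregate_usage,
    delta_sigma,
    fit_zipf_exponent,
    journal_proportions,
    long_tail_summary,
    mean_mentions_per_document,
    name_overlap,
    normalize_to_year0,
    persistence_set,
    random_walk_bounds,
    relative_usage_series,
    top_resources,
)
from resmine.corpus_io import CorpusPartition

from conftest import StubMention


def _mk_partitions(doc_meta, extra=None):
    full = CorpusPartition(name="full",
                           doc_ids=set(doc_meta),
                           journal_names={j for j, _ in doc_meta.values()})
    parts = [full]
    for name, docs in (extra or {}).items():
        parts.append(CorpusPartition(
            name=name, doc_ids=set(docs),
            journal_names={doc_meta[d][0] for d in docs}))
    return parts


def _usage(mention_tuples, doc_meta, extra=None):
    mentions = [StubMention(doc_id=d, span=(0, 3), surface=n, canonical=n)
                for d, n in mention_tuples]
    return aggregate_usage(mentions, _mk_partitions(doc_meta, extra), doc_meta)


class TestAggregateUsage:
    def test_three_mentions_one_doc(self):
        u = _usage([("d1", "BLAST")] * 3, {"d1": ("J", 2010)})
        row = u.partition_df("full").iloc[0]
        assert row["mention_count"] == 3 and row["doc_count"] == 1

    def test_empty_stream(self):
        u = _usage([], {"d1": ("J", 2010)})
        assert len(u.df) == 0 and u.n_docs["full"] == 1

    def test_missing_year_kept_in_all_year_cells(self):
        u = _usage([("d1", "R")], {"d1": ("J", -1)})
        assert u.partition_df("full")["mention_count"].sum() == 1
        assert (u.partition_df("full")["year"] == -1).all()

    def test_matches_naive_recount_on_synthetic_corpus(self, small_corpus):
        """Cell-for-cell agreement with an independent brute-force counter
        over the 100-document gold stream."""
        u = small_corpus.truth_usage()
        naive_m, naive_docs = {}, {}
        for g in small_corpus.gold:
            journal, year = small_corpus.doc_meta[g.doc_id]
            key = (g.name, year, journal)
            naive_m[key] = naive_m.get(key, 0) + 1
            naive_docs.setdefault(key, set()).add(g.doc_id)
        full = u.partition_df("full")
        assert len(full) == len(naive_m)
        for _, row in full.iterrows():
            key = (row["resource"], row["year"], row["journal"])
            assert naive_m[key] == row["mention_count"]
            assert len(naive_docs[key]) == row["doc_count"]


class TestWorkedArithmetic:
    def test_zero_mentions(self):
        assert mean_mentions_per_document(0, 100) == 0.0

    def test_zero_docs_raises(self):
        with pytest.raises(ValueError):
            mean_mentions_per_document(10, 0)

    def test_half_up_rounding(self):
        assert mean_mentions_per_document(125, 1000) == 0.1
        assert mean_mentions_per_document(15, 100) == 0.2  # 0.15 rounds up


class TestTopResources:
    META = {"d1": ("J", 2010), "d2": ("J", 2010), "d3": ("J", 2011),
            "d4": ("J", 2011)}

    def test_document_level_fraction(self):
        u = _usage([("d1", "R"), ("d2", "R"), ("d3", "R"), ("d1", "GO")], self.META)
        rows = dict(top_resources(u, "full", "document", 10))
        assert rows["R"] == 0.75 and rows["GO"] == 0.25

    def test_mention_level_mean(self):
        u = _usage([("d1", "R")] * 6, self.META)
        assert top_resources(u, "full", "mention", 1) == [("R", 1.5)]

    def test_n_larger_than_vocabulary_returns_all(self):
        u = _usage([("d1", "R"), ("d2", "GO")], self.META)
        assert len(top_resources(u, "full", "document", 99)) == 2

    def test_ties_broken_alphabetically(self):
        u = _usage([("d1", "Zeta"), ("d2", "Alpha")], self.META)
        assert [n for n, _ in top_resources(u, "full", "document", 2)] == \
               ["Alpha", "Zeta"]

    def test_unknown_partition_raises(self):
        u = _usage([("d1", "R")], self.META)
        with pytest.raises(KeyError):
            top_resources(u, "nope", "document", 5)


class TestJournalProportions:
    def test_threshold_excludes_small_journals(self):
        doc_meta = {f"a{i}": ("Big J", 2010) for i in range(4)}
        doc_meta.update({f"b{i}": ("Small J", 2010) for i in range(2)})
        u = _usage([("a0", "R")], doc_meta)
        df = journal_proportions(u, min_articles=3)
        assert list(df["journal"]) == ["Big J"]

    def test_zero_mentions_zero_proportion(self):
        doc_meta = {f"a{i}": ("Quiet J", 2010) for i in range(3)}
        u = _usage([], doc_meta)
        df = journal_proportions(u, min_articles=1)
        assert df.loc[0, "proportion"] == 0.0

    def test_proportion_is_mentions_over_articles(self):
        doc_meta = {f"a{i}": ("J", 2010) for i in range(4)}
        u = _usage([("a0", "R")] * 9, doc_meta)
        df = journal_proportions(u, min_articles=1)
        assert df.loc[0, "proportion"] == 2.3  # 9/4 = 2.25 -> half-up 2.3


class TestRelativeUsage:
    def test_pool_fractions_sum_to_one(self):
        doc_meta = {f"d{i}": ("J", 2000 + i % 3) for i in range(30)}
        rng = np.random.default_rng(0)
        mentions = [(f"d{i}", f"res{rng.integers(8)}") for i in range(30)
                    for _ in range(int(rng.integers(1, 4)))]
        u = _usage(mentions, doc_meta)
        series = relative_usage_series(u, "full", [2000, 2001, 2002], pool=5)
        for year in (2000, 2001, 2002):
            total = sum(s.x.get(year, 0.0) for s in series.values())
            assert math.isclose(total, 1.0, abs_tol=1e-9)

    def test_single_resource_corpus(self):
        doc_meta = {"d1": ("J", 2000), "d2": ("J", 2001)}
        u = _usage([("d1", "R"), ("d2", "R")], doc_meta)
        series = relative_usage_series(u, "full", [2000, 2001])
        assert series["R"].x == {2000: 1.0, 2001: 1.0}

    def test_matches_bruteforce_on_fixture(self):
        rng = np.random.default_rng(4)
        doc_meta = {f"d{i}": ("J", 2000 + i % 2) for i in range(40)}
        mentions = [(f"d{i}", f"res{rng.integers(20)}") for i in range(40)]
        u = _usage(mentions, doc_meta)
        pool = 100
        series = relative_usage_series(u, "full", [2000, 2001], pool=pool)
        # brute force: count distinct docs per (resource, year) directly
        for year in (2000, 2001):
            counts = {}
            for d, n in mentions:
                if doc_meta[d][1] == year:
                    counts.setdefault(n, set()).add(d)
            sizes = {n: len(s) for n, s in counts.items()}
            total = sum(sizes.values())
            for n, c in sizes.items():
                assert math.isclose(series[n].x[year], c / total, abs_tol=1e-12)

    def test_non_contiguous_years_rejected(self):
        u = _usage([("d1", "R")], {"d1": ("J", 2000)})
        with pytest.raises(ValueError):
            relative_usage_series(u, "full", [2000, 2002])


class TestYear0:
    def test_constant_series_all_ones(self):
        s = UsageSeries("R", {2000: 0.2, 2001: 0.2, 2002: 0.2})
        assert set(normalize_to_year0(s).x.values()) == {1.0}

    def test_doubling(self):
        s = UsageSeries("R", {2005: 0.02, 2006: 0.04})
        assert normalize_to_year0(s).x == {2005: 1.0, 2006: 2.0}

    def test_singleton(self):
        assert normalize_to_year0(UsageSeries("R", {2003: 0.4})).x == {2003: 1.0}

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            normalize_to_year0(UsageSeries("R", {}))


class TestRandomWalkBounds:
    def test_constant_series_degenerate(self):
        series = [UsageSeries(f"r{i}", {2000: 0.1, 2001: 0.1, 2002: 0.1})
                  for i in range(5)]
        env = random_walk_bounds(series, horizon=4)
        assert env.degenerate
        assert env.bounds(3) == (1.0, 1.0)

    def test_sqrt_t_width_scaling(self):
        rng = np.random.default_rng(1)
        series = [UsageSeries(f"r{i}", {2000 + t: v for t, v in
                                        enumerate(rng.random(6))})
                  for i in range(10)]
        env = random_walk_bounds(series, horizon=8)
        w1 = env.bounds(1)[1] - env.bounds(1)[0]
        w4 = env.bounds(4)[1] - env.bounds(4)[0]
        assert math.isclose(w4, 2 * w1, rel_tol=1e-12)

    def test_width_non_decreasing(self):
        rng = np.random.default_rng(2)
        series = [UsageSeries(f"r{i}", {2000 + t: v for t, v in
                                        enumerate(rng.random(5))})
                  for i in range(6)]
        env = random_walk_bounds(series, horizon=10)
        widths = [env.bounds(t)[1] - env.bounds(t)[0] for t in range(11)]
        assert widths == sorted(widths)

    def test_too_few_steps_raise(self):
        with pytest.raises(ValueError):
            random_walk_bounds([UsageSeries("R", {2000: 0.5})])


class TestDeltaSigma:
    def test_constant_zero(self):
        assert delta_sigma(UsageSeries("R", {2000: 0.3, 2001: 0.3})) == 0.0

    def test_hand_evaluated(self):
        s = UsageSeries("R", {2000: 0.1, 2001: 0.3, 2002: 0.2})
        assert math.isclose(delta_sigma(s), 0.3)

    def test_single_year_empty_sum(self):
        assert delta_sigma(UsageSeries("R", {2005: 0.9})) == 0.0

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(3)
        vals = rng.random(6)
        s1 = UsageSeries("R", {2000 + t: float(v) for t, v in enumerate(vals)})
        s2 = UsageSeries("R", {2000 + t: float(v) + 5.0 for t, v in enumerate(vals)})
        assert math.isclose(delta_sigma(s1), delta_sigma(s2))

    def test_nonnegative_zero_iff_constant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.random(5)
            s = UsageSeries("R", {2000 + t: float(v) for t, v in enumerate(vals)})
            d = delta_sigma(s)
            assert d >= 0.0
            if not np.allclose(vals, vals[0]):
                assert d > 0.0


class TestPersistence:
    def _usage_years(self, per_resource_years):
        doc_meta = {}
        mentions = []
        i = 0
        for name, years in per_resource_years.items():
            for y in years:
                doc = f"d{i}"
                i += 1
                doc_meta[doc] = ("J", y)
                mentions.append((doc, name))
        return _usage(mentions, doc_meta)

    def test_unbroken_recent_run_is_current(self):
        u = self._usage_years({"GEO": range(2003, 2014)})
        recs = persistence_set(u, "full", 2000, 2013)
        assert len(recs) == 1 and recs[0].current and recs[0].unbroken
        assert (recs[0].first_year, recs[0].last_year) == (2003, 2013)

    def test_gap_excludes(self):
        u = self._usage_years({"Gappy": list(range(2003, 2009)) +
                               list(range(2010, 2014))})
        assert persistence_set(u, "full", 2000, 2013) == []

    def test_mention_in_start_year_excludes(self):
        u = self._usage_years({"Oldie": range(2000, 2014)})
        assert persistence_set(u, "full", 2000, 2013) == []

    def test_lapsed_run_not_current(self):
        u = self._usage_years({"Lapsed": range(2004, 2009),
                               "Fresh": range(2010, 2014)})
        recs = {r.resource: r for r in persistence_set(u, "full", 2000, 2013)}
        assert not recs["Lapsed"].current
        assert recs["Fresh"].current


class TestLongTail:
    def test_all_singletons(self):
        doc_meta = {f"d{i}": ("J", 2010) for i in range(5)}
        u = _usage([(f"d{i}", f"res{i}") for i in range(5)], doc_meta)
        lt = long_tail_summary(u, "full")
        assert lt.singleton_fraction == 1.0
        assert lt.singleton_mention_share == 1.0

    def test_zipf_fixture_hand_shares(self):
        counts = [100, 50, 33, 25, 20, 17, 14, 13, 11, 10]
        doc_meta = {}
        mentions = []
        i = 0
        for r, c in enumerate(counts):
            for _ in range(c):
                doc = f"d{i}"
                i += 1
                doc_meta[doc] = ("J", 2010)
                mentions.append((doc, f"res{r:02d}"))
        u = _usage(mentions, doc_meta)
        lt = long_tail_summary(u, "full")
        total = sum(counts)
        assert lt.n_resources == 10
        assert lt.singleton_fraction == 0.0
        assert math.isclose(lt.top_1_share, 100 / total)
        assert math.isclose(lt.top_10_share, 1.0)
        assert lt.top_5pct_names == 1
        assert math.isclose(lt.top_5pct_share, 100 / total)

    def test_empty_partition_raises(self):
        u = _usage([], {"d1": ("J", 2010)})
        with pytest.raises(ValueError):
            long_tail_summary(u, "full")

    def test_top5pct_share_floor_property(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            doc_meta = {}
            mentions = []
            i = 0
            for r in range(n):
                for _ in range(int(rng.integers(1, 9))):
                    doc = f"d{i}"
                    i += 1
                    doc_meta[doc] = ("J", 2010)
                    mentions.append((doc, f"res{r:03d}"))
            lt = long_tail_summary(_usage(mentions, doc_meta), "full")
            assert lt.top_5pct_share >= 0.05


class TestZipfFit:
    def test_recovers_exact_power_law(self):
        ranks = np.arange(1, 200)
        counts = np.round(1e5 * ranks ** -1.3)
        assert abs(fit_zipf_exponent(counts) - 1.3) < 0.02

    def test_needs_two_ranks(self):
        with pytest.raises(ValueError):
            fit_zipf_exponent([10])


class TestNameOverlap:
    def test_disjoint_vocabularies_fully_unique(self):
        doc_meta = {"d1": ("A", 2010), "d2": ("B", 2010)}
        u = _usage([("d1", "X"), ("d2", "Y")], doc_meta,
                   extra={"medicine": ["d1"], "biology": ["d2"]})
        ov = name_overlap(u, ["medicine", "biology"])
        assert ov["medicine"] == {"unique": 1.0}
        assert ov["biology"] == {"unique": 1.0}

    def test_subset_partition_has_no_unique_names(self, small_corpus):
        u = small_corpus.truth_usage()
        ov = name_overlap(u, ["biology", "bioinformatics"])
        assert "unique" not in ov["bioinformatics"]

    def test_hand_built_three_way(self):
        doc_meta = {"d1": ("A", 2010), "d2": ("B", 2010), "d3": ("C", 2010)}
        mentions = [("d1", "Shared"), ("d2", "Shared"), ("d3", "Shared"),
                    ("d1", "MedOnly"), ("d2", "BioPair"), ("d3", "BioPair")]
        u = _usage(mentions, doc_meta,
                   extra={"medicine": ["d1"], "biology": ["d2"],
                          "bioinformatics": ["d3"]})
        ov = name_overlap(u, ["medicine", "biology", "bioinformatics"])
        assert ov["medicine"] == {"bioinformatics+biology": 0.5, "unique": 0.5}
        assert ov["biology"] == {"bioinformatics+medicine": 0.5,
                                 "bioinformatics": 0.5}

    def test_requires_two_partitions(self):
        u = _usage([("d1", "X")], {"d1": ("A", 2010)})
        with pytest.raises(ValueError):
            name_overlap(u, ["full"])
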