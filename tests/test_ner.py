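"""The recogniser: rules, document adjustment, propagation, thresholding."""

import numpy as np
import pytest

from resmine.dictionary import DictionaryEntry, make_dictionary
from resmine.evaluation import evaluate_corpus
from resmine.ner import (
    MentionCandidate,
    adjust_case_length,
    adjust_document_scores,
    apply_rules,
    propagate_document_matches,
    recognize,
    resolve_acronyms,
    threshold_mentions,
)
from resmine.ner.pipeline import find_acronym_definitions
from resmine.ner.rules import RuleMatch, load_rule_config
from resmine.pipeline import extract_corpus_mentions, mentions_by_doc

CFG = load_rule_config()
DICT = make_dictionary([
    DictionaryEntry(canonical="ClustalW", rtype="SW", source="t"),
    DictionaryEntry(canonical="BLAST", rtype="SW", source="t"),
    DictionaryEntry(canonical="GO", rtype="ONT", source="t",
                    expected_expansion="Gene Ontology"),
    DictionaryEntry(canonical="analysis", rtype="SW", source="t"),
])


def _by_surface(cands):
    return {c.surface: c for c in cands}


class TestApplyRules:
    def test_versioned_keyword_dictionary_hit(self):
        text = "sequences were aligned with the ClustalW software (version 2.0)"
        cands = _by_surface(apply_rules(text, DICT, CFG))
        c = cands["ClustalW"]
        assert c.dictionary_hit and c.canonical == "ClustalW"
        assert {1, 2} <= c.rule_ids          # dictionary + version number
        assert c.rule_ids & {5, 9}           # keyword evidence
        assert 16 in c.rule_ids              # "aligned"
        assert c.raw_score > CFG.tau

    def test_negative_keyword_recorded(self):
        cands = _by_surface(apply_rules("our novel clustering algorithm", DICT, CFG))
        assert "clustering" in cands
        assert 6 in cands["clustering"].rule_ids
        assert cands["clustering"].raw_score < 0

    def test_no_hits_no_keywords_empty(self):
        assert apply_rules("the samples were collected carefully", DICT, CFG) == []

    def test_candidates_sorted_by_span(self):
        text = "BLAST output was compared with ClustalW results."
        spans = [c.span for c in apply_rules(text, DICT, CFG)]
        assert spans == sorted(spans)

    def test_common_word_dictionary_hit_penalised(self):
        # bare prose use of an ambiguous name scores below a genuine frame
        bare = _by_surface(apply_rules("a careful analysis of the data", DICT, CFG))
        framed = _by_surface(apply_rules(
            "results were stored in the analysis software", DICT, CFG))
        assert bare["analysis"].raw_score < framed["analysis"].raw_score
        assert 13 in bare["analysis"].rule_ids


class TestDocumentAdjustment:
    def _cand(self, surface, score, span=(0, 5)):
        c = MentionCandidate(surface=surface, span=span)
        c.raw_score = score
        return c

    def test_repeated_weak_positive_cohort_gains(self):
        weak = [self._cand("Tool", 1.0, (i * 10, i * 10 + 4)) for i in range(5)]
        single = [self._cand("Other", 1.0)]
        adjust_document_scores(weak, CFG)
        adjust_document_scores(single, CFG)
        assert all(c.adjusted_score > c.raw_score for c in weak)
        assert single[0].adjusted_score == single[0].raw_score

    def test_singleton_no_bonus(self):
        c = self._cand("Tool", 1.5)
        adjust_document_scores([c], CFG)
        assert c.adjusted_score == c.raw_score

    def test_all_negative_cohort_floored(self):
        cs = [self._cand("method", -1.0, (i * 10, i * 10 + 6)) for i in range(4)]
        adjust_document_scores(cs, CFG)
        assert all(c.adjusted_score == c.raw_score for c in cs)

    def test_never_decreases_any_score(self):
        rng = np.random.default_rng(0)
        cs = [self._cand(f"s{i % 3}", float(rng.normal()), (i * 10, i * 10 + 2))
              for i in range(30)]
        adjust_document_scores(cs, CFG)
        assert all(c.adjusted_score >= c.raw_score for c in cs)


class TestPropagation:
    TEXT = ("We processed everything with the velveth software (version 1.0). "
            "The velveth output was archived. "
            "Later velveth runs used identical settings. "
            "Output from velveth was merged.")

    def test_bare_occurrences_promoted_with_flag(self):
        cands = apply_rules(self.TEXT, DICT, CFG)
        adjust_document_scores(cands, CFG)
        before = len(cands)
        out = propagate_document_matches(cands, self.TEXT, CFG)
        promoted = [c for c in out if 15 in c.rule_ids]
        assert len(out) > before
        assert len(promoted) == 3
        assert all(c.adjusted_score >= CFG.tau for c in promoted)

    def test_no_seed_no_change(self):
        text = "a careful analysis of the data was repeated"
        cands = apply_rules(text, DICT, CFG)
        adjust_document_scores(cands, CFG)
        out = propagate_document_matches(cands, text, CFG)
        assert out == cands

    def test_never_invents_surface_forms(self):
        cands = apply_rules(self.TEXT, DICT, CFG)
        adjust_document_scores(cands, CFG)
        out = propagate_document_matches(cands, self.TEXT, CFG)
        for c in out:
            assert self.TEXT[c.span[0]:c.span[1]] == c.surface

    def test_propagation_never_removes(self):
        cands = apply_rules(self.TEXT, DICT, CFG)
        adjust_document_scores(cands, CFG)
        out = propagate_document_matches(cands, self.TEXT, CFG)
        assert {c.span for c in cands} <= {c.span for c in out}


class TestAcronyms:
    def test_definition_matching_expected_accepted(self):
        doc = "Annotations came from the Gene Ontology (GO) project."
        m = MentionCandidate(surface="GO", span=(0, 2), dictionary_hit=True)
        assert resolve_acronyms(m, doc, DICT, 0.2)

    def test_conflicting_definition_rejected(self):
        doc = "Samples were treated with glucose oxidase (GO) overnight."
        m = MentionCandidate(surface="GO", span=(0, 2), dictionary_hit=True)
        assert not resolve_acronyms(m, doc, DICT, 0.2)

    def test_no_definition_passes_through(self):
        doc = "GO terms were assigned to each gene."
        m = MentionCandidate(surface="GO", span=(0, 2), dictionary_hit=True)
        assert resolve_acronyms(m, doc, DICT, 0.2)

    def test_detector_finds_long_form(self):
        defs = find_acronym_definitions(
            "We queried the Protein Data Bank (PDB) for structures.")
        assert defs.get("PDB") == "Protein Data Bank"


class TestCaseLength:
    def test_short_all_caps_rewarded(self):
        assert adjust_case_length(1.0, "BLAST", CFG) >= 1.0

    def test_lowercase_common_word_penalised(self):
        assert adjust_case_length(1.0, "analysis", CFG) < 1.0

    def test_long_mixed_case_unchanged(self):
        assert adjust_case_length(1.0, "VeryLongMixedName", CFG) == 1.0

    def test_monotone_in_score(self):
        for surface in ("BLAST", "analysis", "ClustalW"):
            lo = adjust_case_length(0.0, surface, CFG)
            hi = adjust_case_length(1.0, surface, CFG)
            assert hi > lo


class TestThreshold:
    def _cands(self, scores):
        out = []
        for i, s in enumerate(scores):
            c = MentionCandidate(surface=f"s{i}", span=(i * 10, i * 10 + 2))
            c.raw_score = s
            c.adjusted_score = s
            out.append(c)
        return out

    def test_minus_infinity_accepts_all(self):
        cands = self._cands([0.1, -5.0, 3.0])
        assert len(threshold_mentions(cands, float("-inf"))) == 3

    def test_above_max_rejects_all(self):
        cands = self._cands([0.1, 3.0])
        assert threshold_mentions(cands, 99.0) == []

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cands = self._cands(rng.normal(size=10))
            taus = sorted(rng.normal(size=4))
            counts = [len(threshold_mentions(cands, t)) for t in taus]
            assert counts == sorted(counts, reverse=True)

    def test_output_sorted_by_span(self):
        cands = self._cands([5.0, 5.0, 5.0])[::-1]
        spans = [m.span for m in threshold_mentions(cands, 0.0)]
        assert spans == sorted(spans)


class TestRecognizer:
    def test_deterministic(self, small_corpus):
        a = small_corpus.articles[0]
        m1 = recognize(a, small_corpus.dictionary)
        m2 = recognize(a, small_corpus.dictionary)
        assert [(m.span, m.surface, m.adjusted_score, sorted(m.rule_ids))
                for m in m1] == \
               [(m.span, m.surface, m.adjusted_score, sorted(m.rule_ids))
                for m in m2]

    def test_caption_mentions_live_in_caption_stream(self, small_corpus):
        arts = [a for a in small_corpus.articles if a.captions]
        mentions = recognize(arts[0], small_corpus.dictionary)
        for m in mentions:
            if m.stream == "caption":
                assert m.section == "caption"
                assert m.caption_index is not None

    def test_prefilter_strict_f_on_synthetic_gold(self, small_corpus):
        """The unfiltered recogniser clears strict F >= 0.6 on default-style
        synthetic gold, mirroring its pre-filter operating point."""
        mentions = extract_corpus_mentions(small_corpus.articles,
                                           small_corpus.dictionary)
        _, s = evaluate_corpus(small_corpus.gold_body_spans(),
                               mentions_by_doc(mentions), mode="strict")
        assert s.f1 >= 0.6


class TestRuleMatchInvariants:
    def test_unknown_rule_id_rejected(self):
        with pytest.raises(ValueError):
            RuleMatch(rule_id=18, weight=1.0, span=(0, 1))

    def test_polarity_follows_weight_sign(self):
        assert RuleMatch(6, -1.5, (0, 1)).polarity == "negative"
        assert RuleMatch(5, 1.0, (0, 1)).polarity == "positive"
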