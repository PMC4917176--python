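"""Candidate generation, rule firing, scoring and thresholding.

The recogniser proceeds in stages over one document at a time:

1. ``apply_rules`` — generate candidate spans (dictionary n-gram matches,
   capitalised tokens, nouns attached to category keywords) and fire the
   contextual rules; ``raw_score`` is the sum of matched rule weights,
   including the case/length adjustment.
2. ``adjust_document_scores`` — candidates sharing a normalised surface form
   receive a non-negative cohort bonus, so several weak clues scattered over
   a document can jointly cross the threshold.
3. ``propagate_document_matches`` — every bare occurrence of a surface form
   whose best cohort member crossed the threshold is promoted to a candidate.
4. ``resolve_acronyms`` — acronym candidates whose in-text long form
   contradicts the dictionary's expected expansion are rejected.
5. ``threshold_mentions`` — accept candidates with adjusted score >= tau.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib

from .._util import normalize_name
from ..corpus_io import Article
from ..dictionary import Dictionary
from .preprocess import ADJ, NOUN, NUM, PROPN, PUNCT, REF, URL, VERB, Sentence, preprocess
from .rules import RuleConfig, RuleMatch, load_rule_config

_ACRONYM_RE = re.compile(r"^[A-Z][A-Z0-9]{1,5}$")
_VERSION_WORD = {"version", "v", "ver", "release", "build"}
_CANDIDATE_TAGS = {NOUN, PROPN, VERB, ADJ}


@dataclass
class MentionCandidate:
    surface: str
    span: tuple[int, int]
    matched_rules: dict[int, RuleMatch] = field(default_factory=dict)
    raw_score: float = 0.0
    adjusted_score: float | None = None
    dictionary_hit: bool = False
    canonical: str | None = None
    stream: str = "body"
    caption_index: int | None = None

    @property
    def rule_ids(self) -> frozenset[int]:
        return frozenset(self.matched_rules)


@dataclass
class Mention(MentionCandidate):
    doc_id: str = ""
    accepted: bool = False
    section: str | None = None
    filter_confidence: float | None = None


def adjust_case_length(score: float, surface: str, config: RuleConfig | None = None) -> float:
    """Piecewise case/length score adjustment.

    Short all-caps surfaces (acronym-shaped) and short mixed-case surfaces
    are rewarded; all-lowercase common-word surfaces are penalised; long
    mixed-case surfaces (>= 12 characters) pass through unchanged.  Additive,
    hence monotone in the underlying score.
    """
    config = config or _default_config()
    return score + _case_delta(surface, config)


def _case_delta(surface: str, config: RuleConfig) -> float:
    compact = surface.replace(" ", "")
    if _ACRONYM_RE.match(compact) and 2 <= len(compact) <= 6:
        return config.weights[12]
    if surface.lower() in config.common_words and surface == surface.lower():
        return config.weights[13]
    if len(surface) < 12 and any(c.isupper() for c in surface[1:]):
        return config.mixed_bonus
    return 0.0


_CONFIG_CACHE: RuleConfig | None = None


def _default_config() -> RuleConfig:
    global _CONFIG_CACHE
    if _CONFIG_CACHE is None:
        _CONFIG_CACHE = load_rule_config()
    return _CONFIG_CACHE


# ---------------------------------------------------------------------------
# candidate generation


def _ngram_matches(sentences: list[Sentence], index: dict[str, object],
                   max_tokens: int,
                   validate=None) -> list[tuple[int, int, str, object]]:
    """Longest-match left-to-right n-gram scan over token sequences.

    Returns (start, end, surface, payload) for non-overlapping matches of
    normalised token n-grams present in ``index``.  ``validate(surface,
    payload)`` may veto a hit (returning None), in which case shorter n-grams
    at the same position are still tried.
    """
    out = []
    for sent in sentences:
        toks = sent.tokens
        i = 0
        while i < len(toks):
            if toks[i].tag in (PUNCT, REF, URL):
                i += 1
                continue
            matched = None
            for n in range(min(max_tokens, len(toks) - i), 0, -1):
                window = toks[i:i + n]
                if any(t.tag == PUNCT for t in window):
                    continue
                surface = " ".join(t.text for t in window)
                key = normalize_name(surface)
                if key and key in index:
                    payload = index[key]
                    if validate is not None:
                        payload = validate(surface, payload)
                        if payload is None:
                            continue
                    matched = (toks[i].start, window[-1].end, surface, payload, n)
                    break
            if matched:
                out.append(matched[:4])
                i += matched[4]
            else:
                i += 1
    return out


def _sentence_of(sentences: list[Sentence], start: int) -> tuple[int, Sentence] | None:
    for si, s in enumerate(sentences):
        if s.start <= start < s.end:
            return si, s
    return None


def _token_index_range(sent: Sentence, span: tuple[int, int]) -> tuple[int, int]:
    """Indices [i, j] of the sentence tokens covered by a character span."""
    lo, hi = None, None
    for k, t in enumerate(sent.tokens):
        if t.end > span[0] and t.start < span[1]:
            if lo is None:
                lo = k
            hi = k
    if lo is None:  # span not over any token (should not happen)
        lo = hi = 0
    return lo, hi


def apply_rules(doc: str | list[Sentence], d: Dictionary,
                config: RuleConfig | None = None) -> list[MentionCandidate]:
    """Generate candidates and fire the contextual rules.

    ``doc`` may be a raw string (preprocessed here) or an existing sentence
    list.  Dictionary hits generate candidates even with no contextual rule;
    nouns attached to category keywords (positive or negative) are candidates
    too, so negative evidence is recorded rather than silently dropped.
    """
    config = config or _default_config()
    sentences = preprocess(doc) if isinstance(doc, str) else doc

    dict_index = {k: True for k in d.variant_index}
    max_n = d.max_variant_tokens()
    covered: set[tuple[int, int]] = set()
    candidates: list[MentionCandidate] = []

    def literal(surface, payload):
        # case-sensitive confirmation: keeps short all-caps entries ("GO",
        # "ON") from matching ordinary prose words
        return payload if d.lookup_exact(surface) else None

    for start, end, surface, _ in _ngram_matches(sentences, dict_index, max_n,
                                                 validate=literal):
        cand = MentionCandidate(surface=surface, span=(start, end),
                                dictionary_hit=True,
                                canonical=d.canonical_for(surface))
        cand.matched_rules[1] = RuleMatch(1, config.weights[1], (start, end))
        candidates.append(cand)
        covered.add((start, end))

    # single-token candidates: proper nouns and keyword-attached nouns
    keywords = (config.positive_keywords | config.negative_keywords
                | config.restricted_heads)
    for sent in sentences:
        toks = sent.tokens
        for k, t in enumerate(toks):
            if t.tag not in _CANDIDATE_TAGS or t.text.lower() in keywords:
                continue
            if any(s <= t.start and t.end <= e for s, e in covered):
                continue
            is_propn = t.tag == PROPN
            before_kw = k + 1 < len(toks) and toks[k + 1].text.lower() in keywords
            if not (is_propn or before_kw):
                continue
            span = (t.start, t.end)
            if span in covered:
                continue
            candidates.append(MentionCandidate(surface=t.text, span=span))
            covered.add(span)

    for cand in candidates:
        _fire_contextual_rules(cand, sentences, config)
        _score_candidate(cand, config)
    candidates.sort(key=lambda c: c.span)
    return candidates


def _fire_contextual_rules(cand: MentionCandidate, sentences: list[Sentence],
                           config: RuleConfig) -> None:
    loc = _sentence_of(sentences, cand.span[0])
    if loc is None:
        return
    _, sent = loc
    toks = sent.tokens
    lo, hi = _token_index_range(sent, cand.span)
    w = config.keyword_window
    span = cand.span

    def add(rule_id: int, s=None) -> None:
        if rule_id not in cand.matched_rules:
            cand.matched_rules[rule_id] = RuleMatch(rule_id, config.weights[rule_id],
                                                    s or span)

    # rule 2: version number shortly after the candidate
    for k in range(hi + 1, min(hi + 4, len(toks))):
        t = toks[k]
        low = t.text.lower().rstrip(".")
        if t.tag == NUM and ("." in t.text or low in _VERSION_WORD):
            add(2, (t.start, t.end)); break
        if low in _VERSION_WORD:
            add(2, (t.start, t.end)); break

    # rule 3: URL in window; rule 4: citation marker just after
    for k in range(max(0, lo - 5), min(hi + 6, len(toks))):
        if toks[k].tag == URL:
            add(3, (toks[k].start, toks[k].end)); break
    for k in range(hi + 1, min(hi + 3, len(toks))):
        if toks[k].tag == REF:
            add(4, (toks[k].start, toks[k].end)); break

    # rules 5/6: positive/negative keyword within the window
    for k in range(max(0, lo - w), min(hi + 1 + w, len(toks))):
        if lo <= k <= hi:
            continue
        low = toks[k].text.lower()
        if low in config.positive_keywords:
            add(5, (toks[k].start, toks[k].end))
        elif low in config.negative_keywords:
            add(6, (toks[k].start, toks[k].end))

    # rule 7: Hearst category pattern — "KW(s) such as X" / "KW(s) including X"
    for k in range(len(toks)):
        low = toks[k].text.lower()
        if low not in config.positive_keywords and low not in config.restricted_heads:
            continue
        nxt = [t.text.lower() for t in toks[k + 1:k + 3]]
        hearst = (nxt[:2] == ["such", "as"]) or (nxt[:1] == ["including"]) or (nxt[:1] == ["like"])
        if hearst and k < lo <= k + 8:
            add(7, (toks[k].start, toks[k].end))
            break

    # rule 8: apposition — "X, a(n) ... KW"
    if hi + 2 < len(toks) and toks[hi + 1].text == ",":
        for k in range(hi + 2, min(hi + 7, len(toks))):
            low = toks[k].text.lower()
            if low in config.positive_keywords:
                add(8, (toks[k].start, toks[k].end)); break
            if toks[k].tag in (PUNCT, VERB):
                break

    # rules 9/10: head-keyword association via the shallow head links
    head_idx = toks[hi].head
    head_low = toks[head_idx].text.lower() if head_idx is not None else ""
    nxt_low = toks[hi + 1].text.lower() if hi + 1 < len(toks) else ""
    if head_low in config.positive_keywords or nxt_low in config.positive_keywords:
        add(9)
    elif head_low in config.restricted_heads or nxt_low in config.restricted_heads:
        add(10)

    # rule 16: usage-verb context
    for k in range(max(0, lo - 3), min(hi + 4, len(toks))):
        if lo <= k <= hi:
            continue
        if toks[k].text.lower() in config.usage_verbs:
            add(16, (toks[k].start, toks[k].end))
            break

    # rule 17: capitalised out-of-dictionary token mid-sentence
    if not cand.dictionary_hit and toks[lo].tag == PROPN and lo > 0:
        add(17)

    # rules 12/13: case/length shape
    delta = _case_delta(cand.surface, config)
    if delta > 0 and _ACRONYM_RE.match(cand.surface.replace(" ", "")):
        add(12)
    elif delta < 0:
        add(13)
    elif delta > 0:
        add(12)


def _score_candidate(cand: MentionCandidate, config: RuleConfig) -> None:
    """raw_score = sum of matched rule weights, with two twists: the
    restricted-head rule only contributes when corroborated by another
    positive rule, and rules 12/13 contribute the case/length delta."""
    positive_other = any(
        rid not in (10, 12, 13, 14, 15) and m.weight > 0
        for rid, m in cand.matched_rules.items()
    )
    score = 0.0
    for rid, m in cand.matched_rules.items():
        if rid in (12, 13):
            continue
        if rid == 10 and not positive_other:
            continue
        score += m.weight
    score += _case_delta(cand.surface, config)
    cand.raw_score = score


# ---------------------------------------------------------------------------
# document-level stages


def adjust_document_scores(candidates: list[MentionCandidate],
                           config: RuleConfig | None = None) -> list[MentionCandidate]:
    """Add a non-negative cohort bonus to candidates sharing a surface form.

    bonus = min(cap, rate * (k - 1) * mean positive raw score of the cohort),
    floored at zero — repetition plus positive evidence helps, repetition of
    purely negative evidence does not.  Never decreases any score.
    """
    config = config or _default_config()
    cohorts: dict[str, list[MentionCandidate]] = {}
    for c in candidates:
        cohorts.setdefault(normalize_name(c.surface), []).append(c)
    for members in cohorts.values():
        k = len(members)
        mean_pos = sum(max(m.raw_score, 0.0) for m in members) / k
        bonus = min(config.cohort_cap, config.cohort_rate * (k - 1) * mean_pos)
        bonus = max(bonus, 0.0)
        for m in members:
            m.adjusted_score = m.raw_score + bonus
            if bonus > 0:
                m.matched_rules.setdefault(14, RuleMatch(14, config.weights[14], m.span))
    return candidates


def propagate_document_matches(candidates: list[MentionCandidate],
                               doc: str | list[Sentence],
                               config: RuleConfig | None = None,
                               d: Dictionary | None = None) -> list[MentionCandidate]:
    """Promote bare occurrences of surface forms that crossed the threshold.

    Occurrences inherit the best adjusted score of their seed cohort and are
    flagged with the propagation rule.  Never removes candidates and never
    invents a surface form absent from the document.
    """
    config = config or _default_config()
    sentences = preprocess(doc) if isinstance(doc, str) else doc
    seeds: dict[str, MentionCandidate] = {}
    for c in candidates:
        if c.adjusted_score is not None and c.adjusted_score >= config.tau:
            key = normalize_name(c.surface)
            if key not in seeds or c.adjusted_score > seeds[key].adjusted_score:
                seeds[key] = c
    if not seeds:
        return candidates
    taken = {c.span for c in candidates}
    max_n = max(len(k.split()) for k in seeds)
    out = list(candidates)

    def case_ok(surface, seed):
        # propagate the literal surface; other case variants only when the
        # dictionary itself sanctions them
        if surface == seed.surface:
            return seed
        if d is not None and any(e.canonical == seed.canonical
                                 for e in d.lookup_exact(surface)):
            return seed
        return None if d is not None else seed

    for start, end, surface, seed in _ngram_matches(sentences, seeds, max_n,
                                                    validate=case_ok):
        if (start, end) in taken or any(
                s < end and start < e for s, e in taken):
            continue
        promoted = MentionCandidate(
            surface=surface, span=(start, end),
            dictionary_hit=seed.dictionary_hit, canonical=seed.canonical,
            raw_score=0.0, adjusted_score=seed.adjusted_score,
        )
        promoted.matched_rules[15] = RuleMatch(15, config.weights[15], (start, end))
        if seed.dictionary_hit:
            promoted.matched_rules[1] = RuleMatch(1, config.weights[1], (start, end))
        out.append(promoted)
        taken.add((start, end))
    out.sort(key=lambda c: c.span)
    return out


# ---------------------------------------------------------------------------
# acronym screening


def find_acronym_definitions(doc: str | list[Sentence]) -> dict[str, str]:
    """Parenthesis-style long-form detection ("Long Form (LF)").

    For each all-caps 2–6 token alone in parentheses, scan left up to
    |acronym| + 5 tokens for the shortest token suffix whose word initials
    contain the acronym's letters in order.
    """
    sentences = preprocess(doc) if isinstance(doc, str) else doc
    defs: dict[str, str] = {}
    for sent in sentences:
        toks = sent.tokens
        for k in range(1, len(toks) - 1):
            if (toks[k - 1].text == "(" and toks[k + 1].text == ")"
                    and _ACRONYM_RE.match(toks[k].text)):
                acro = toks[k].text
                window = [t for t in toks[max(0, k - 1 - (len(acro) + 5)):k - 1]
                          if t.tag not in (PUNCT, REF)]
                if not window:
                    continue
                letters = [c for c in acro.lower() if c.isalpha()]
                best = None
                for i in range(len(window)):
                    suffix = window[i:]
                    initials = [t.text[0].lower() for t in suffix]
                    if _subsequence(letters, initials):
                        best = suffix
                if best is None:
                    best = window[-len(letters):] if len(window) >= len(letters) else window
                defs.setdefault(acro, " ".join(t.text for t in best))
    return defs


def _subsequence(needle: list[str], haystack: list[str]) -> bool:
    it = iter(haystack)
    return all(ch in it for ch in needle)


def normalized_edit_distance(a: str, b: str) -> float:
    a, b = a.casefold(), b.casefold()
    if not a and not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def resolve_acronyms(m: MentionCandidate, doc: str | list[Sentence] | dict[str, str],
                     d: Dictionary, tolerance: float = 0.2) -> bool:
    """Accept/reject an acronym candidate against its expected expansion.

    If the document defines the acronym in parenthesis style, the detected
    long form must match the dictionary's expected expansion within the
    normalised-edit-distance tolerance; with no in-text definition the
    candidate passes through unchanged.  Returns True to keep the candidate.
    """
    compact = m.surface.replace(" ", "")
    if not _ACRONYM_RE.match(compact) or len(compact) > 6:
        return True
    entries = d.lookup(m.surface)
    expected = next((e.expected_expansion for e in entries if e.expected_expansion), None)
    if expected is None:
        return True
    defs = doc if isinstance(doc, dict) else find_acronym_definitions(doc)
    detected = defs.get(compact)
    if detected is None:
        return True
    return normalized_edit_distance(detected, expected) <= tolerance


# ---------------------------------------------------------------------------
# thresholding and the one-call document pipeline


def threshold_mentions(candidates: list[MentionCandidate], tau: float,
                       doc_id: str = "") -> list[Mention]:
    """Accept candidates with adjusted score >= tau, sorted by span."""
    out = []
    for c in sorted(candidates, key=lambda c: c.span):
        score = c.adjusted_score if c.adjusted_score is not None else c.raw_score
        if score >= tau:
            out.append(Mention(
                surface=c.surface, span=c.span, matched_rules=dict(c.matched_rules),
                raw_score=c.raw_score, adjusted_score=score,
                dictionary_hit=c.dictionary_hit, canonical=c.canonical,
                stream=c.stream, caption_index=c.caption_index,
                doc_id=doc_id, accepted=True,
                section="caption" if c.stream == "caption" else None,
            ))
    return out


def _recognize_stream(text: str, d: Dictionary, config: RuleConfig,
                      doc_id: str, stream: str,
                      caption_index: int | None = None) -> list[Mention]:
    if not text:
        return []
    sentences = preprocess(text)
    cands = apply_rules(sentences, d, config)
    cands = adjust_document_scores(cands, config)
    cands = propagate_document_matches(cands, sentences, config, d)
    defs = find_acronym_definitions(sentences)
    cands = [c for c in cands
             if resolve_acronyms(c, defs, d, config.acronym_tolerance)]
    for c in cands:
        if c.dictionary_hit and c.surface.replace(" ", "") in defs:
            c.matched_rules.setdefault(11, RuleMatch(11, config.weights[11], c.span))
    mentions = threshold_mentions(cands, config.tau, doc_id=doc_id)
    for m in mentions:
        m.stream = stream
        m.caption_index = caption_index
        if stream == "caption":
            m.section = "caption"
    return mentions


def recognize(article: Article, d: Dictionary,
              config: RuleConfig | None = None) -> list[Mention]:
    """Run the full recogniser over one article: body plus caption streams.

    Deterministic: identical input and config give an identical mention list.
    """
    config = config or _default_config()
    mentions = _recognize_stream(article.body, d, config, article.doc_id, "body")
    for i, cap in enumerate(article.captions):
        mentions.extend(
            _recognize_stream(cap, d, config, article.doc_id, "caption", i))
    return mentions
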