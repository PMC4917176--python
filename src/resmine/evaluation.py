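"""Strict/lenient span evaluation and ranking metrics.

Strict scoring requires gold and system offsets to match exactly; lenient
scoring accepts any character overlap.  Matching is one-to-one and
cardinality-maximal (maximum bipartite matching over the overlap graph),
with larger overlaps and left-most spans preferred among equal-cardinality
assignments, so a strict match is always also a lenient match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

Span = tuple[int, int]


@dataclass(frozen=True)
class MatchResult:
    mode: str
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class Scores:
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True


def _check_spans(spans, what: str) -> list[Span]:
    out = []
    for s in spans:
        start, end = s
        if end <= start:
            raise ValueError(f"malformed {what} span {s!r}: end <= start")
        out.append((int(start), int(end)))
    return out


def _overlap(a: Span, b: Span) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def match_spans(gold, system, mode: str = "strict") -> MatchResult:
    """One-to-one span matching within a single document.

    strict: a pair matches iff spans are identical; lenient: iff they overlap
    by at least one character.  The assignment maximises the number of matched
    pairs; among maximal assignments, pairs with larger overlap and left-most
    position are preferred.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    gold = sorted(_check_spans(gold, "gold"))
    system = sorted(_check_spans(system, "system"))
    if not gold or not system:
        return MatchResult(mode=mode, tp=0, fp=len(system), fn=len(gold))

    pairs = []
    for gi, g in enumerate(gold):
        for si, s in enumerate(system):
            ov = _overlap(g, s)
            ok = (g == s) if mode == "strict" else ov > 0
            if ok:
                pairs.append((gi, si, ov))
    if not pairs:
        return MatchResult(mode=mode, tp=0, fp=len(system), fn=len(gold))

    # order candidate edges greedily (overlap desc, left-most first); the
    # matching below keeps cardinality maximal regardless of this order
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    graph = csr_matrix((np.ones(len(pairs), dtype=np.int8), (rows, cols)),
                       shape=(len(gold), len(system)))
    assignment = maximum_bipartite_matching(graph, perm_type="column")
    tp = int((assignment >= 0).sum())
    return MatchResult(mode=mode, tp=tp, fp=len(system) - tp, fn=len(gold) - tp)


def score_prf(r: MatchResult) -> Scores:
    """Precision, recall and F1 from match counts.

    Empty denominators are flagged undefined and reported as 0 (with a log
    warning) rather than raising.
    """
    p_def = (r.tp + r.fp) > 0
    r_def = (r.tp + r.fn) > 0
    if not p_def:
        logger.warning("precision undefined (no system spans); reporting 0")
    if not r_def:
        logger.warning("recall undefined (no gold spans); reporting 0")
    p = r.tp / (r.tp + r.fp) if p_def else 0.0
    rec = r.tp / (r.tp + r.fn) if r_def else 0.0
    f1 = 2 * p * rec / (p + rec) if (p + rec) > 0 else 0.0
    return Scores(precision=p, recall=rec, f1=f1,
                  precision_defined=p_def, recall_defined=r_def)


def evaluate_corpus(gold_by_doc: dict, system_by_doc: dict,
                    mode: str = "strict") -> tuple[MatchResult, Scores]:
    """Pool match counts over documents (keys = doc ids, values = span lists)."""
    tp = fp = fn = 0
    for doc_id in set(gold_by_doc) | set(system_by_doc):
        r = match_spans(gold_by_doc.get(doc_id, []),
                        system_by_doc.get(doc_id, []), mode=mode)
        tp, fp, fn = tp + r.tp, fp + r.fp, fn + r.fn
    result = MatchResult(mode=mode, tp=tp, fp=fp, fn=fn)
    return result, score_prf(result)


def score_auc(predictions) -> float:
    """Rank-based AUC (Mann-Whitney) with ties averaged.

    ``predictions`` is an iterable of (score, label) with truthy labels
    positive.  Requires both classes present.
    """
    scores = np.array([float(s) for s, _ in predictions])
    labels = np.array([bool(l) for _, l in predictions])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative examples")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
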