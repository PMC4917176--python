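"""Rule-profile post-processing filter.

Accepted mentions are re-scored by a classifier trained purely on which of
the 17 recognition rules each mention matched (17 binary flags plus the
matched-rule count — 18 features, deliberately no lexical or morpho-syntactic
information, so the filter cannot overfit to surface strings).  Mentions the
classifier is confidently sure are false positives (P(FP) >= the confidence
cut, default 0.80) are removed; this trades recall for precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import score_auc
from .ner.rules import N_RULES, RULE_IDS

FAMILIES = ("naive_bayes", "svm_linear", "svm_rbf", "random_forest", "c45")

FP_LABEL = "false_positive"
TP_LABEL = "true_positive"


@dataclass(frozen=True)
class FeatureVector:
    rule_flags: tuple[int, ...]  # 17 binary indicators, rule ids 1..17
    rule_count: int

    def __post_init__(self) -> None:
        if len(self.rule_flags) != N_RULES:
            raise ValueError(f"expected {N_RULES} rule flags")
        if self.rule_count != sum(self.rule_flags):
            raise ValueError("rule_count must equal the number of set flags")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.rule_flags) + [self.rule_count], dtype=float)


@dataclass(frozen=True)
class LabeledMention:
    features: FeatureVector
    label: str  # TP_LABEL or FP_LABEL
    alignment_mode: str = "lenient"


def featurize(mention_or_rules) -> FeatureVector:
    """Encode a mention (or bare rule-id set) as 17 flags + rule count."""
    rule_ids = getattr(mention_or_rules, "rule_ids", None)
    if rule_ids is None:
        rule_ids = frozenset(mention_or_rules)
    bad = set(rule_ids) - set(RULE_IDS)
    if bad:
        raise ValueError(f"rule ids outside the published inventory: {sorted(bad)}")
    flags = tuple(1 if rid in rule_ids else 0 for rid in RULE_IDS)
    return FeatureVector(rule_flags=flags, rule_count=sum(flags))


def label_mentions(mentions, gold_spans: Sequence[tuple[int, int]],
                   mode: str = "lenient") -> list[LabeledMention]:
    """Label system mentions of one document stream against gold spans.

    A mention is a true positive if it overlaps (lenient) or exactly matches
    (strict) some gold span; one-to-one multiplicity is not enforced here —
    labelling is per-mention, which is what the filter needs.
    """
    out = []
    for m in mentions:
        if mode == "strict":
            is_tp = tuple(m.span) in {tuple(g) for g in gold_spans}
        else:
            is_tp = any(min(m.span[1], g[1]) - max(m.span[0], g[0]) > 0
                        for g in gold_spans)
        out.append(LabeledMention(features=featurize(m),
                                  label=TP_LABEL if is_tp else FP_LABEL,
                                  alignment_mode=mode))
    return out


def label_corpus(mentions, gold_by_doc: Mapping[str, Sequence[tuple[int, int]]],
                 mode: str = "lenient") -> list[LabeledMention]:
    """Label a whole corpus of body-stream mentions against per-doc gold."""
    by_doc: dict[str, list] = {}
    for m in mentions:
        if getattr(m, "stream", "body") == "body":
            by_doc.setdefault(m.doc_id, []).append(m)
    out: list[LabeledMention] = []
    for doc_id, doc_mentions in by_doc.items():
        out.extend(label_mentions(doc_mentions, gold_by_doc.get(doc_id, []), mode=mode))
    return out


@dataclass
class FilterModel:
    family: str
    estimator: object
    seed: int
    metadata: dict = field(default_factory=dict)

    def predict_fp_proba(self, X: np.ndarray) -> np.ndarray:
        """P(false positive) per row, in [0, 1]."""
        proba = self.estimator.predict_proba(X)
        fp_col = list(self.estimator.classes_).index(FP_LABEL)
        return proba[:, fp_col]


def _make_estimator(family: str, seed: int):
    if family == "naive_bayes":
        return BernoulliNB()
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if family == "svm_linear":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if family == "c45":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


def _to_xy(data: Sequence[LabeledMention]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([d.features.as_array() for d in data])
    y = np.array([d.label for d in data])
    return X, y


def train_filter(data: Sequence[LabeledMention], family: str = "random_forest",
                 seed: int = 0) -> FilterModel:
    """Fit a filter model on labelled mentions; reproducible given seed."""
    X, y = _to_xy(data)
    present = set(y)
    for cls in (TP_LABEL, FP_LABEL):
        if cls not in present:
            raise ValueError(f"training data has no {cls} examples")
    est = _make_estimator(family, seed)
    est.fit(X, y)
    return FilterModel(family=family, estimator=est, seed=seed,
                       metadata={"n_train": len(y),
                                 "alignment_mode": data[0].alignment_mode})


def cross_validate(data: Sequence[LabeledMention],
                   families: Iterable[str] = ("naive_bayes", "random_forest"),
                   folds: int = 10, repeats: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """Repeated stratified k-fold model comparison.

    The data are shuffled ``repeats`` times; each shuffle runs a ``folds``-fold
    cross-validation.  Precision/recall/F1 are for the false-positive class
    (the filter's target); AUC ranks P(FP).  Per-repeat metrics come from the
    pooled fold confusion counts; the report rows are mean and std over
    repeats per family.
    """
    X, y = _to_xy(data)
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds dataset size {len(y)}")
    rows = []
    for family in families:
        per_repeat = []
        for rep in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed * 1000 + rep)
            tp = fp = fn = 0
            preds: list[tuple[float, bool]] = []
            for train_idx, test_idx in skf.split(X, y):
                est = _make_estimator(family, seed * 1000 + rep)
                est.fit(X[train_idx], y[train_idx])
                yhat = est.predict(X[test_idx])
                ytrue = y[test_idx]
                tp += int(((yhat == FP_LABEL) & (ytrue == FP_LABEL)).sum())
                fp += int(((yhat == FP_LABEL) & (ytrue == TP_LABEL)).sum())
                fn += int(((yhat == TP_LABEL) & (ytrue == FP_LABEL)).sum())
                proba = est.predict_proba(X[test_idx])
                fp_col = list(est.classes_).index(FP_LABEL)
                preds.extend(zip(proba[:, fp_col], ytrue == FP_LABEL))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            per_repeat.append((p, r, f1, score_auc(preds)))
        arr = np.array(per_repeat)
        std = (lambda col: float(col.std(ddof=1))) if repeats > 1 else (lambda col: 0.0)
        rows.append({
            "family": family,
            "precision_mean": arr[:, 0].mean(), "precision_std": std(arr[:, 0]),
            "recall_mean": arr[:, 1].mean(), "recall_std": std(arr[:, 1]),
            "f1_mean": arr[:, 2].mean(), "f1_std": std(arr[:, 2]),
            "auc_mean": arr[:, 3].mean(), "auc_std": std(arr[:, 3]),
        })
    return pd.DataFrame(rows).set_index("family")


def apply_filter(mentions, model: FilterModel, confidence: float = 0.80):
    """Remove mentions the model is at least ``confidence`` sure are FPs.

    The boundary is removal: P(FP) exactly at the cut goes.  Retained
    mentions keep their confidence for audit.  Returns the retained list.
    """
    mentions = list(mentions)
    if not mentions:
        return []
    X = np.stack([featurize(m).as_array() for m in mentions])
    p_fp = model.predict_fp_proba(X)
    retained = []
    for m, p in zip(mentions, p_fp):
        m.filter_confidence = float(p)
        if p < confidence:
            retained.append(m)
    return retained
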