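"""The fixed 17-rule inventory and its configuration.

Rule ids are stable and published here so that downstream rule-profile
features (one binary feature per rule) keep their meaning across runs.
Weights, keyword lists, the acceptance threshold tau and the fuzzy acronym
tolerance all live in a JSON config; the defaults shipped in
``resmine/data/default_rules.json`` were calibrated once on the synthetic
gold corpus and are not tied to any particular document collection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

#: rule id -> short name.  Positive/negative polarity follows the weight sign.
RULE_NAMES: dict[int, str] = {
    1: "dictionary",
    2: "version_number",
    3: "url_adjacent",
    4: "reference_adjacent",
    5: "positive_keyword",
    6: "negative_keyword",
    7: "hearst_category",
    8: "apposition",
    9: "head_association",
    10: "restricted_head",
    11: "acronym_defined",
    12: "case_shape",
    13: "common_word",
    14: "cohort_adjusted",
    15: "propagated",
    16: "usage_verb",
    17: "capitalised_oov",
}
RULE_IDS = tuple(sorted(RULE_NAMES))
N_RULES = len(RULE_IDS)


@dataclass(frozen=True)
class RuleMatch:
    rule_id: int
    weight: float
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_NAMES:
            raise ValueError(f"unknown rule id {self.rule_id}")

    @property
    def polarity(self) -> str:
        return "negative" if self.weight < 0 else "positive"


@dataclass
class RuleConfig:
    """Keyword lists, rule weights, threshold and tolerances."""

    weights: dict[int, float]
    tau: float
    positive_keywords: set[str]
    negative_keywords: set[str]
    restricted_heads: set[str]
    usage_verbs: set[str]
    common_words: set[str]
    acronym_tolerance: float = 0.2
    cohort_rate: float = 0.35
    cohort_cap: float = 2.0
    keyword_window: int = 3
    mixed_bonus: float = 0.3

    def weight(self, rule_id: int) -> float:
        return self.weights[rule_id]

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        weights = {int(k): float(v) for k, v in d["weights"].items()}
        missing = set(RULE_IDS) - set(weights)
        if missing:
            raise ValueError(f"rule weights missing for ids {sorted(missing)}")
        return cls(
            weights=weights,
            tau=float(d["tau"]),
            positive_keywords=set(d["positive_keywords"]),
            negative_keywords=set(d["negative_keywords"]),
            restricted_heads=set(d["restricted_heads"]),
            usage_verbs=set(d["usage_verbs"]),
            common_words=set(d["common_words"]),
            acronym_tolerance=float(d.get("acronym_tolerance", 0.2)),
            cohort_rate=float(d.get("cohort_rate", 0.35)),
            cohort_cap=float(d.get("cohort_cap", 2.0)),
            keyword_window=int(d.get("keyword_window", 3)),
            mixed_bonus=float(d.get("mixed_bonus", 0.3)),
        )


def load_rule_config(path: str | Path | None = None) -> RuleConfig:
    """Load a rule config from JSON; with no path, the shipped defaults."""
    if path is None:
        text = resources.files("resmine.data").joinpath("default_rules.json").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return RuleConfig.from_dict(json.loads(text))
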