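"""Document zoning: label rhetorical sections from heading text.

Headings are matched against an editable regular-expression table mapping
heading text classes to one of {introduction, methods, results_discussion,
conclusion}; results and discussion are a single category because journals
frequently merge them.  Each detected heading opens a span ending at the next
heading (or document end); text before the first heading is ``other``.
Mentions are assigned the label of the span containing their start offset;
caption-stream mentions are a separate stream and are never zoned.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .corpus_io import Article

SECTION_LABELS = ("introduction", "methods", "results_discussion", "conclusion", "other")


@dataclass(frozen=True)
class SectionSpan:
    label: str
    start: int
    end: int


class PatternTable:
    """Ordered (compiled regex, label) pairs; first full match wins."""

    def __init__(self, patterns: list[tuple[str, str]]):
        self.patterns = [(re.compile(p, re.IGNORECASE), label) for p, label in patterns]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternTable":
        rows = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            pattern, label = line.split("\t")
            if label.strip() not in SECTION_LABELS:
                raise ValueError(f"unknown section label {label!r}")
            rows.append((pattern.strip(), label.strip()))
        return cls(rows)

    @classmethod
    def default(cls) -> "PatternTable":
        with resources.as_file(
            resources.files("resmine.data").joinpath("heading_patterns.tsv")
        ) as p:
            return cls.from_tsv(p)

    def classify(self, heading: str) -> str:
        text = heading.strip().rstrip(".:").strip()
        for rx, label in self.patterns:
            if rx.fullmatch(text):
                return label
        return "other"


def label_sections(a: Article, patterns: PatternTable | None = None) -> list[SectionSpan]:
    """Non-overlapping, sorted section spans jointly covering [0, len(body))."""
    patterns = patterns or PatternTable.default()
    n = len(a.body)
    if n == 0:
        return []
    spans: list[SectionSpan] = []
    headings = sorted(a.heading_spans, key=lambda h: h[1])
    if not headings or headings[0][1] > 0:
        first = headings[0][1] if headings else n
        spans.append(SectionSpan(label="other", start=0, end=first))
    for i, (text, start, _end) in enumerate(headings):
        nxt = headings[i + 1][1] if i + 1 < len(headings) else n
        spans.append(SectionSpan(label=patterns.classify(text), start=start, end=nxt))
    return spans


def assign_section(m, spans: list[SectionSpan]):
    """Set ``m.section`` to the label of the span containing its start offset.

    A mention straddling a boundary takes the section of its start.  Caption
    mentions keep their "caption" label untouched.
    """
    if getattr(m, "stream", "body") == "caption":
        m.section = "caption"
        return m
    start = m.span[0]
    if not spans or not (spans[0].start <= start < spans[-1].end):
        raise ValueError(f"mention start {start} outside zoned body")
    starts = [s.start for s in spans]
    m.section = spans[bisect_right(starts, start) - 1].label
    return m


def zone_mentions(article: Article, mentions, patterns: PatternTable | None = None):
    """Label an article's sections and assign every body mention to one."""
    spans = label_sections(article, patterns)
    for m in mentions:
        assign_section(m, spans)
    return mentions


def section_usage_table(mentions, n_docs: int, top_n: int = 10):
    """Per-section top-N resources by fraction of documents mentioning them.

    ``mentions`` must carry doc_id, canonical (or surface) and section.
    Returns {section: [(name, fraction), ...]} ranked by fraction then name.
    """
    import pandas as pd

    if n_docs < 0:
        raise ValueError("n_docs must be >= 0")
    rows = [(m.section or "other", m.canonical or m.surface, m.doc_id)
            for m in mentions]
    if not rows or n_docs == 0:
        return {}
    df = pd.DataFrame(rows, columns=["section", "name", "doc_id"])
    out: dict[str, list[tuple[str, float]]] = {}
    for section, grp in df.groupby("section"):
        counts = grp.drop_duplicates(["name", "doc_id"]).groupby("name").size()
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        out[section] = [(name, cnt / n_docs) for name, cnt in ranked]
    return out
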