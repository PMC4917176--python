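"""End-to-end convenience wrappers over the module surface."""

from __future__ import annotations

from typing import Iterable, Sequence

from .corpus_io import Article
from .dictionary import Dictionary
from .ner import Mention, recognize
from .ner.rules import RuleConfig
from .zoning import PatternTable, zone_mentions


def extract_corpus_mentions(articles: Iterable[Article], d: Dictionary,
                            config: RuleConfig | None = None,
                            patterns: PatternTable | None = None) -> list[Mention]:
    """Recognise and zone mentions over a whole corpus, article by article."""
    patterns = patterns or PatternTable.default()
    mentions: list[Mention] = []
    for a in articles:
        doc_mentions = recognize(a, d, config)
        zone_mentions(a, [m for m in doc_mentions if m.stream == "body"], patterns)
        mentions.extend(doc_mentions)
    return mentions


def mentions_by_doc(mentions: Sequence[Mention],
                    stream: str = "body") -> dict[str, list[tuple[int, int]]]:
    """Group mention spans per document for span evaluation."""
    out: dict[str, list[tuple[int, int]]] = {}
    for m in mentions:
        if m.stream == stream:
            out.setdefault(m.doc_id, []).append(m.span)
    return out
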