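"""Resource-name dictionary: loading, variant expansion, and statistics.

The recogniser is seeded by a dictionary of known database/software/package/
ontology names compiled from several source lists.  Each row of a dictionary
TSV is ``canonical<TAB>rtype<TAB>source[<TAB>expansion]``; the same canonical
name may appear under several sources (it then counts once per source, as the
source lists are audited independently), while the *variant index* collapses
all normalised surface variants into shared keys.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import normalize_name

logger = logging.getLogger(__name__)

RESOURCE_TYPES = frozenset({"DB", "SW", "PK", "ONT", "unknown"})

_CAMEL_SPLIT = re.compile(r"(?<=[a-z])(?=[A-Z])")


@dataclass(frozen=True)
class DictionaryEntry:
    """One dictionary row: a canonical resource name plus generated variants."""

    canonical: str
    rtype: str = "unknown"
    source: str = "manual"
    expected_expansion: str | None = None
    variants: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical name must be non-empty")
        variants = set(self.variants) | {self.canonical}
        object.__setattr__(self, "variants", frozenset(variants))


def expand_variants(canonical: str) -> set[str]:
    """Generate deterministic surface variants of a canonical name.

    Rules: case variants (as-is, lower, upper); hyphen/space alternation
    ("SWISS-PROT" -> "SWISS PROT", "SWISSPROT"); camel-case splitting
    ("ClustalW" -> "Clustal W"); and a trailing-version-stripped form
    ("BLAST 2.0" -> "BLAST").  Idempotent on its own outputs modulo
    normalisation.
    """
    if not canonical:
        raise ValueError("canonical name must be non-empty")
    base = {canonical.strip()}
    # hyphen/space alternation
    for v in list(base):
        if "-" in v:
            base.add(v.replace("-", " "))
            base.add(v.replace("-", ""))
    # camel-case split ("ClustalW" -> "Clustal W")
    for v in list(base):
        split = _CAMEL_SPLIT.sub(" ", v)
        if split != v:
            base.add(split)
    # trailing version stripped
    for v in list(base):
        stripped = re.sub(r"[\s]*v?\d+(?:\.\d+)+$", "", v).strip()
        if stripped and stripped != v:
            base.add(stripped)
    # case variants last, over everything generated so far.  Short all-caps
    # names (GO, ON, PDB) never gain a lowercase variant: they would collide
    # with ordinary prose words and must match case-sensitively.
    out = set()
    for v in base:
        out.add(v)
        if len(v) >= 5 or not v.isupper():
            out.add(v.lower())
        if len(v) > 1 and not v.isupper():
            out.add(v.capitalize())
        if len(v) > 1:
            out.add(v.upper())
        elif v.isalpha():  # single letters: both cases ("r" <-> "R")
            out.add(v.upper())
    return {v for v in out if v}


@dataclass
class Dictionary:
    """A loaded dictionary plus an index from normalised variant to entries."""

    entries: list[DictionaryEntry] = field(default_factory=list)
    variant_index: dict[str, set[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def rebuild_index(self) -> None:
        self.variant_index = {}
        for i, e in enumerate(self.entries):
            for v in e.variants:
                self.variant_index.setdefault(normalize_name(v), set()).add(i)
        self.variant_index.pop("", None)

    def lookup(self, surface: str) -> list[DictionaryEntry]:
        """All entries whose variant set covers ``surface`` (normalised)."""
        ids = self.variant_index.get(normalize_name(surface), set())
        return [self.entries[i] for i in sorted(ids)]

    def lookup_exact(self, surface: str) -> list[DictionaryEntry]:
        """Entries holding ``surface`` as a literal (case-sensitive) variant.

        The normalised index narrows the candidates; the literal check keeps
        short all-caps entries from swallowing ordinary prose words.
        """
        collapsed = " ".join(surface.split())
        ids = self.variant_index.get(normalize_name(surface), set())
        return [self.entries[i] for i in sorted(ids)
                if collapsed in self.entries[i].variants]

    def canonical_for(self, surface: str) -> str | None:
        hits = self.lookup(surface)
        return hits[0].canonical if hits else None

    def max_variant_tokens(self) -> int:
        return max((len(v.split()) for v in self.variant_index), default=1)


def make_dictionary(entries: Iterable[DictionaryEntry]) -> Dictionary:
    """Build a Dictionary from entries, expanding variants and indexing."""
    full = []
    seen: set[tuple[str, str]] = set()
    for e in entries:
        key = (e.canonical, e.source)
        if key in seen:
            continue
        seen.add(key)
        full.append(
            DictionaryEntry(
                canonical=e.canonical,
                rtype=e.rtype if e.rtype in RESOURCE_TYPES else "unknown",
                source=e.source,
                expected_expansion=e.expected_expansion,
                variants=frozenset(e.variants | expand_variants(e.canonical)),
            )
        )
    d = Dictionary(entries=full)
    d.rebuild_index()
    return d


def load_dictionary(files: Sequence[str | Path]) -> Dictionary:
    """Load and merge one or more dictionary TSV files.

    Rows are deduplicated per (canonical, source).  Unknown resource types are
    kept with rtype="unknown" and logged; unreadable files raise with the
    offending path in the message.
    """
    entries: list[DictionaryEntry] = []
    for path in files:
        path = Path(path)
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot read dictionary file {path}: {exc}") from exc
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            canonical, rtype, source = cols[0].strip(), cols[1].strip(), cols[2].strip()
            expansion = cols[3].strip() if len(cols) > 3 and cols[3].strip() else None
            if rtype not in RESOURCE_TYPES:
                logger.warning("%s:%d: unknown rtype %r, keeping as 'unknown'", path, lineno, rtype)
                rtype = "unknown"
            entries.append(
                DictionaryEntry(canonical=canonical, rtype=rtype, source=source,
                                expected_expansion=expansion)
            )
    return make_dictionary(entries)


def dictionary_stats(d: Dictionary) -> tuple[int, int, Mapping[str, int]]:
    """(total_entries, unique_variants, per_source counts).

    total_entries is the sum of per-source counts (an entry listed by two
    sources counts twice, matching how source lists are audited); the unique
    variant count is over normalised variants pooled across all entries.
    """
    per_source: dict[str, int] = {}
    variants: set[str] = set()
    for e in d.entries:
        per_source[e.source] = per_source.get(e.source, 0) + 1
        variants.update(normalize_name(v) for v in e.variants)
    variants.discard("")
    return sum(per_source.values()), len(variants), per_source
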