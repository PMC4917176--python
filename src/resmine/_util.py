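"""Small shared helpers: rounding and name normalisation."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_WS = re.compile(r"\s+")
_TRAILING_VERSION = re.compile(
    r"[\s,]*(?:\(?(?:v|ver|version)\.?\s*\d+(?:\.\d+)*[a-z]?\)?|\d+(?:\.\d+)+[a-z]?)$",
    re.IGNORECASE,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's built-in round() is banker's rounding; reported proportions and
    means here use conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_name(name: str) -> str:
    """Normalise a resource-name variant for indexing and cohort grouping.

    Case-folds, collapses internal whitespace and hyphen/underscore runs to a
    single space, and strips a trailing version token ("v2.0", "1.3.1", ...).
    Aggressive by design: many surface variants should collapse to one key.
    """
    s = name.strip()
    s = _TRAILING_VERSION.sub("", s)
    s = s.replace("-", " ").replace("_", " ")
    s = _WS.sub(" ", s).strip()
    return s.casefold()
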