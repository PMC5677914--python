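"""Small shared helpers: half-up rounding and star-name ordering."""
from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_STAR_RE = re.compile(r"^\*(\d+)([A-Za-z0-9>._]*)$")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal precision.

    Reported percentages use this rule (banker's rounding would turn e.g.
    96.5 into 96 instead of 97).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numer: int, denom: int, ndigits: int = 0) -> float | None:
    """Percentage with half-up rounding; ``None`` when the denominator is 0."""
    if denom == 0:
        return None
    return round_half_up(100.0 * numer / denom, ndigits)


def star_sort_key(name: str) -> tuple:
    """Ordering key for star-allele names: *2 < *10 < *35; non-star names last.

    Used to put diplotypes in canonical (hap1, hap2) order.
    """
    m = _STAR_RE.match(name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, name)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a star pair canonically (low star number first)."""
    return (a, b) if star_sort_key(a) <= star_sort_key(b) else (b, a)
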