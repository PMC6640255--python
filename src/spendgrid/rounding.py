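"""Reporting-precision helpers.

Aggregate currency is reported to the nearest million dollars and shares to
integer or one-decimal percent, rounding half away from zero in every case.
All computation upstream stays in exact integer cents; these helpers are the
only place precision is dropped.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

CENTS_PER_MILLION_DOLLARS = 100_000_000


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (1.5 -> 2, -1.5 -> -2)."""
    q = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(rounded)


def cents_to_millions(cents: int | float, ndigits: int = 0) -> float:
    """Express cents as (rounded) millions of dollars."""
    return round_half_away(float(cents) / CENTS_PER_MILLION_DOLLARS, ndigits)


def share_pct(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage share at reporting precision; ``whole`` must be nonzero."""
    if whole == 0:
        raise ZeroDivisionError("cannot take a share of a zero total")
    return round_half_away(100.0 * part / whole, ndigits)
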