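"""Shared report formatting: half-up rounding and percentage helpers.

Report tables round percentages half-up (not banker's rounding) to one
decimal, the convention used in genome-statistics tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """part/whole as a percentage, rounded half-up."""
    if whole == 0:
        raise ValueError("zero denominator")
    return round_half_up(100.0 * part / whole, ndigits)
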