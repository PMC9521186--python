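"""Small shared helpers: display rounding and ratio formatting.

Percentages are displayed to one decimal and rates per 100 person-years to
two decimals, both rounded half-up (the convention of the source tables,
which differs from Python's banker's rounding).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

STUDY_SCAN_START = "2007-01-01"
STUDY_ENROL_START = "2009-01-01"
STUDY_ENROL_END = "2019-12-01"  # last admissible index discharge
STUDY_END = "2019-12-31"

DAYS_PER_YEAR = 365.25


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, e.g. 54.35 -> 54.4 at one decimal."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def share_percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage numerator/denominator, half-up rounded for display.

    Raises ValueError on a zero denominator (an undefined proportion is a
    caller error, not a 0%).
    """
    if denominator == 0:
        raise ValueError("proportion undefined: zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
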