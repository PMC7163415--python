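"""Exact decimal rounding helpers.

Reported percentages follow the print convention of clinical journals:
round half-up to one decimal.  Python's builtin ``round`` is banker's
rounding and float division is inexact at the boundary, so percentages
are computed with :mod:`decimal` from the integer numerator/denominator.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (0.25 -> 0.3 at 1 digit)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator, denominator, ndigits: int = 1) -> float:
    """100 * numerator / denominator, half-up to ``ndigits`` decimals.

    A zero or missing denominator yields NaN (percent "reported as
    missing") rather than raising.
    """
    if denominator is None or (isinstance(denominator, float) and math.isnan(denominator)):
        return float("nan")
    if denominator == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
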