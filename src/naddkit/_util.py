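"""Shared numeric helpers (report-style rounding)."""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals.

    Python's built-in round() is banker's rounding; report tables here follow
    the half-away-from-zero convention instead (3.195 -> 3.2, -0.125 -> -0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    ndigits = sig - 1 - exponent
    return round_half_away(x, ndigits)
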