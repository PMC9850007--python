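"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of printed
    report tables), unlike Python's banker's rounding."""
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return x
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quant, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded; NaN for a zero
    denominator."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, ndigits)
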