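"""Small shared numeric helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as printed reports do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mean_sd(values) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation.

    The sd is ``None`` for fewer than two values.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("mean_sd requires at least one value")
    n = len(vals)
    mean = sum(vals) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var)
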