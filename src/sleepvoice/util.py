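"""Small shared helpers: presentation rounding and Gaussian AIC."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), for presentation only.

    Stored values are never rounded; this is applied when percentages or
    two-decimal metrics are rendered, so that e.g. 11/16 prints as 68.8%.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: float, ndigits: int = 1) -> float:
    """Proportion -> percentage, half-up rounded."""
    return round_half_up(100.0 * x, ndigits)


def gaussian_aic(rss: float, n: int, edf: float) -> float:
    """AIC for a Gaussian model with residual sum of squares `rss`.

    Uses the maximum-likelihood variance estimate rss/n and counts the
    variance as one extra parameter on top of the model's `edf` effective
    degrees of freedom.  Both the ordinary least-squares fit and the
    penalized-spline additive fit are scored with this same function so
    their AIC values are directly comparable.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rss = max(rss, 1e-300)
    return n * math.log(2 * math.pi * rss / n) + n + 2 * (edf + 1)
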