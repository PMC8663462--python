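"""Wilson score intervals for tag proportions.

Corpus summaries report k-of-n tag frequencies with 95% CIs computed by
the score method (the interval R's ``prop.test`` produces without
continuity correction).  The uncorrected variant is deliberate: it is the
one that reproduces printed intervals such as 66/78 -> 75%-91% and
4/99 -> 1.6%-9.9%, which the corrected interval does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .formats import round_half_up

__all__ = ["ProportionCI", "wilson_ci"]


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    conf: float
    z: float
    p_hat: float
    lower: float
    upper: float

    def rounded_pct(self, decimals: int = 0) -> tuple[float, float]:
        """Endpoints on the percent scale at printed precision (half-up)."""
        return (round_half_up(100 * self.lower, decimals),
                round_half_up(100 * self.upper, decimals))


def wilson_ci(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion, no continuity
    correction.

    centre = (p + z^2/2n) / (1 + z^2/n) and half-width
    z/(1 + z^2/n) * sqrt(p(1-p)/n + z^2/4n^2), with z the standard-normal
    quantile at 1-(1-conf)/2.  At k=0 the lower endpoint is exactly 0 and
    at k=n the upper endpoint is exactly 1.
    """
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not (0.0 < conf < 1.0):
        raise ValueError("conf must lie in (0, 1)")
    z = float(norm.ppf(1.0 - (1.0 - conf) / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    lower = 0.0 if k == 0 else max(0.0, centre - half)
    upper = 1.0 if k == n else min(1.0, centre + half)
    return ProportionCI(k=k, n=n, conf=conf, z=z, p_hat=p,
                        lower=lower, upper=upper)
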