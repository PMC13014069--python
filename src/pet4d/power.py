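"""Two-group sample-size calculation by exact noncentral-t power.

Answers "how many subjects per group detect the observed VT difference?"
for a two-sided, pooled-variance two-sample t-test: at candidate group size
n the test statistic under the alternative follows a noncentral t with
df = 2n - 2 and noncentrality |mean_A - mean_B| * sqrt(n/2) / SD; the
smallest n whose power reaches the target is returned (the ``power.t.test``
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "two_sample_t_power", "two_sample_t_sample_size"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for an equal-allocation two-group comparison of means."""

    mean_a: float
    mean_b: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")

    @property
    def effect_size(self) -> float:
        return abs(self.mean_a - self.mean_b) / self.sd


def two_sample_t_power(effect_size: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled-variance t-test at n per group."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = effect_size * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def two_sample_t_sample_size(spec: PowerSpec, n_max: int = 10**6) -> tuple[int, float]:
    """Smallest integer n per group with power >= target.

    Returns ``(n, achieved_power)``.
    """
    if spec.mean_a == spec.mean_b:
        raise ValueError("equal group means: required n is unbounded")
    d = spec.effect_size
    # normal-approximation lower envelope to start the scan near the answer
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    n = max(2, int(np.floor(2.0 * (za + zb) ** 2 / d**2)) - 2)
    while n <= n_max:
        p = two_sample_t_power(d, n, spec.alpha)
        if p >= spec.power:
            # guard against overshooting the smallest n from the warm start
            while n > 2 and two_sample_t_power(d, n - 1, spec.alpha) >= spec.power:
                n -= 1
            return n, two_sample_t_power(d, n, spec.alpha)
        n += 1
    raise RuntimeError("sample size search exceeded n_max")
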