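"""Closed-form power for binary-outcome Mendelian randomisation.

Follows the standard non-centrality argument for an IVW estimate with a
binary outcome: with total sample size ``n``, instrument R^2 on the
exposure, case fraction ``p`` and target odds ratio ``OR``, the power of a
two-sided level-``alpha`` test is

    Phi( |ln OR| * sqrt(n * R^2 * p * (1 - p)) - z_{1 - alpha/2} ).

``case_to_control_ratio`` is the number of controls per case, so
``p = 1 / (1 + ratio)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    n_total: int
    r2: float
    alpha: float
    case_to_control_ratio: float
    or_target: float

    def validate(self) -> None:
        if self.n_total <= 0 or self.case_to_control_ratio <= 0 or self.or_target <= 0:
            raise ValueError("n_total, case_to_control_ratio and or_target must be positive")
        for name in ("r2", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


def mr_power(q: PowerQuery) -> float:
    """Power of the IVW test; symmetric in OR vs 1/OR, monotone in n, R^2, |ln OR|."""
    q.validate()
    p = 1.0 / (1.0 + q.case_to_control_ratio)
    z_crit = stats.norm.ppf(1.0 - q.alpha / 2.0)
    ncp = abs(math.log(q.or_target)) * math.sqrt(q.n_total * q.r2 * p * (1.0 - p))
    return float(stats.norm.cdf(ncp - z_crit))
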