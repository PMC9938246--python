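"""Fixed-effects inverse-variance meta-analysis of per-cohort odds ratios.

Per-cohort MR results are typically published as an OR with a 95% CI.  The
combination works on the log scale: the SE is recovered from the CI width
as ``(ln upper - ln lower) / (2 * 1.959964)``, cohorts are combined with
inverse-variance weights, and the result is exponentiated back.  The
6-decimal normal quantile (rather than 1.96) minimises rounding drift when
recombining printed 2-decimal tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mr import Z95


@dataclass(frozen=True)
class CohortEstimate:
    """One cohort's OR (95% CI) with its derived log-scale representation."""

    cohort_name: str
    or_point: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float

    @classmethod
    def from_or_ci(cls, cohort_name: str, or_point: float, ci_low: float,
                   ci_high: float) -> "CohortEstimate":
        log_or, se = or_ci_to_log(or_point, ci_low, ci_high)
        return cls(cohort_name, or_point, ci_low, ci_high, log_or, se)


@dataclass(frozen=True)
class MetaResult:
    """Combined fixed-effects estimate with normalised weights and heterogeneity."""

    log_or: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pval: float
    weights: dict[str, float]
    q_stat: float
    q_df: int
    q_p: float | None


def or_ci_to_log(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Convert an OR with 95% CI to (log-OR, SE); rejects degenerate inputs."""
    for name, v in (("or_point", or_point), ("ci_low", ci_low), ("ci_high", ci_high)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    if not (ci_low <= or_point <= ci_high):
        raise ValueError(
            f"CI ordering violated: need ci_low <= or <= ci_high, got {ci_low}, {or_point}, {ci_high}"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if not se > 0:
        raise ValueError(f"ci_low and ci_high give non-positive se ({se}); CI must have width")
    return math.log(or_point), se


def fixed_effects_meta(estimates: Sequence[CohortEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects combination of per-cohort log-ORs."""
    if not estimates:
        raise ValueError("no cohort estimates to combine")
    log_ors = np.array([e.log_or for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses**2
    sw = w.sum()
    log_or = float((w * log_ors).sum() / sw)
    se = float(sw**-0.5)
    q = float((w * (log_ors - log_or) ** 2).sum())
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else None
    pval = float(2.0 * stats.norm.sf(abs(log_or / se)))
    weights = {e.cohort_name: float(wi / sw) for e, wi in zip(estimates, w)}
    return MetaResult(
        log_or=log_or, se=se, or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se), ci_high=math.exp(log_or + Z95 * se),
        pval=pval, weights=weights, q_stat=q, q_df=q_df, q_p=q_p,
    )
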