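"""Two-sample MR estimators and sensitivity analyses.

Given harmonised per-variant effects (gamma_j, se_gamma_j) on the exposure
and (Gamma_j, se_Gamma_j) on the outcome, the causal log-odds per SD
exposure is estimated by:

* the per-variant Wald ratio ``Gamma_j / gamma_j`` with first-order delta
  SE ``se_Gamma_j / |gamma_j|``;
* fixed-effects inverse-variance-weighted (IVW) pooling of the ratios,
  algebraically identical to zero-intercept weighted least squares of
  Gamma on gamma with weights 1/se_Gamma^2;
* MR-Egger regression (free intercept; a non-zero intercept indicates
  directional pleiotropy under the InSIDE assumption);
* the weighted median (consistent when variants carrying >= 50% of the
  weight are valid instruments), with a parametric-bootstrap SE;
* leave-one-out IVW;
* MR-PRESSO: a simulation-based residual-sum-of-squares global test for
  horizontal pleiotropy with per-variant outlier detection and an
  outlier-corrected IVW estimate.

All estimators are invariant to jointly sign-flipping (gamma_j, Gamma_j)
for any variant.  SEs are fixed-effect (no multiplicative overdispersion
scaling); Cochran's Q is reported where applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary import HarmonisedInstrument, InstrumentSet

#: two-sided 95% normal quantile, kept at 6 decimals to match CI<->SE conversions
Z95 = 1.959964


@dataclass(frozen=True)
class MrResult:
    """One estimator's output: log-odds slope per SD exposure with 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    label: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class PressoReport:
    """MR-PRESSO global test, per-SNP outlier p-values, and corrected estimate."""

    global_rss: float
    global_p: float
    n_sim: int
    per_snp_p: tuple[float, ...]
    outlier_indices: tuple[int, ...]
    outlier_ids: tuple[str, ...]
    corrected: MrResult | None


def _result(method, beta, se, nsnp, **kw) -> MrResult:
    beta, se = float(beta), float(se)
    pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else math.nan
    return MrResult(
        method=method, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=float(pval), nsnp=int(nsnp), **kw,
    )


def _arrays(instruments):
    """Extract (gamma, gamma_se, Gamma, Gamma_se, ids) from a set or sequence."""
    if isinstance(instruments, InstrumentSet):
        seq: Sequence[HarmonisedInstrument] = instruments.instruments
    else:
        seq = instruments
    seq = [h for h in seq if h.usable]
    if not seq:
        raise ValueError("no usable instruments")
    gamma = np.array([h.exposure_beta for h in seq])
    gse = np.array([h.exposure_se for h in seq])
    Gamma = np.array([h.outcome_beta for h in seq])
    Gse = np.array([h.outcome_se for h in seq])
    ids = [h.snp_id for h in seq]
    return gamma, gse, Gamma, Gse, ids


def wald_ratio(inst: HarmonisedInstrument) -> MrResult:
    """Single-variant causal estimate: outcome effect over exposure effect."""
    if not inst.usable:
        raise ValueError(f"{inst.snp_id}: not a usable instrument ({inst.action})")
    if inst.exposure_beta == 0:
        raise ValueError(f"{inst.snp_id}: undefined Wald ratio (exposure beta is 0)")
    beta = inst.outcome_beta / inst.exposure_beta
    se = inst.outcome_se / abs(inst.exposure_beta)
    return _result("wald", beta, se, 1, label=inst.snp_id)


def ivw_fixed(instruments) -> MrResult:
    """Fixed-effects IVW estimate across all instruments.

    Weights are ``w_j = gamma_j^2 / se_Gamma_j^2`` (the inverse variance of
    the first-order Wald ratio); the pooled slope is the weighted mean of
    the ratios with ``se = (sum w)^{-1/2}``, and Cochran's Q measures
    heterogeneity of the ratios around it.
    """
    gamma, _, Gamma, Gse, _ = _arrays(instruments)
    if np.any(gamma == 0):
        raise ValueError("exposure beta of 0 present; Wald ratios undefined")
    w = gamma**2 / Gse**2
    ratios = Gamma / gamma
    sw = w.sum()
    beta = float((w * ratios).sum() / sw)
    se = float(sw**-0.5)
    q = float((w * (ratios - beta) ** 2).sum())
    j = len(gamma)
    q_df = j - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else None
    return _result("ivw_fixed", beta, se, j, q_stat=q, q_df=q_df, q_p=q_p)


def egger(instruments, t_dist: bool = False) -> MrResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    All pairs are first oriented so the exposure effect is positive (jointly
    flipping both betas), making the intercept interpretable as the average
    directional pleiotropic effect.  SEs come from the fixed-effect
    information matrix ``(X' W X)^{-1}``; p-values use the standard normal
    by default or a t reference with J-2 df when ``t_dist`` is set.
    """
    gamma, _, Gamma, Gse, _ = _arrays(instruments)
    j = len(gamma)
    if j < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {j}")
    if np.any(gamma == 0):
        raise ValueError("exposure beta of 0 present")
    s = np.sign(gamma)
    x = gamma * s
    y = Gamma * s
    if np.ptp(x) == 0:
        raise ValueError("zero variance in exposure effects; Egger slope unidentified")
    w = 1.0 / Gse**2
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    se_slope = math.sqrt(sw / det)
    se_int = math.sqrt(swxx / det)
    if t_dist:
        pz = lambda b, se: 2.0 * stats.t.sf(abs(b / se), df=j - 2)
    else:
        pz = lambda b, se: 2.0 * stats.norm.sf(abs(b / se))
    res = y - intercept - slope * x
    q = float((w * res**2).sum())
    out = _result(
        "egger", slope, se_slope, j,
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_p=float(pz(intercept, se_int)),
        q_stat=q, q_df=j - 2, q_p=float(stats.chi2.sf(q, j - 2)),
    )
    if t_dist:
        object.__setattr__(out, "pval", float(pz(slope, se_slope)))
    return out


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, ws = ratios[order], w[order]
    cw = np.cumsum(ws)
    s = (cw - 0.5 * ws) / cw[-1]
    return float(np.interp(0.5, s, r))


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratios are sorted and the estimate interpolated at cumulative normalised
    weight 0.5; the SE is the SD of the estimate over ``n_boot`` parametric
    resamples of (gamma, Gamma) from their normal sampling distributions,
    fully determined by ``seed``.
    """
    gamma, gse, Gamma, Gse, _ = _arrays(instruments)
    j = len(gamma)
    if j < 2:
        raise ValueError(f"weighted median needs >= 2 instruments, got {j}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if np.any(gamma == 0):
        raise ValueError("exposure beta of 0 present")
    w = gamma**2 / Gse**2
    est = _weighted_median(Gamma / gamma, w)
    rng = np.random.default_rng(seed)
    gs = rng.normal(gamma, gse, size=(n_boot, j))
    Gs = rng.normal(Gamma, Gse, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        wb = gs[b] ** 2 / Gse**2
        boots[b] = _weighted_median(Gs[b] / gs[b], wb)
    se = float(boots.std(ddof=1))
    return _result("weighted_median", est, se, j)


def leave_one_out(instruments) -> list[MrResult]:
    """IVW re-estimated J times, each time excluding one SNP (labelled by it)."""
    if isinstance(instruments, InstrumentSet):
        seq = [h for h in instruments.instruments if h.usable]
    else:
        seq = [h for h in instruments if h.usable]
    if len(seq) < 2:
        raise ValueError("leave-one-out needs >= 2 instruments")
    out = []
    for i, h in enumerate(seq):
        rest = seq[:i] + seq[i + 1 :]
        r = ivw_fixed(rest)
        out.append(
            MrResult(**{**r.__dict__, "method": "ivw_loo", "label": h.snp_id})
        )
    return out


def mr_presso(
    instruments,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoReport:
    """MR-PRESSO global pleiotropy test with outlier detection and correction.

    The observed statistic is the weighted residual sum of squares
    ``sum_j (Gamma_j - beta_{-j} gamma_j)^2 / se_Gamma_j^2`` where
    ``beta_{-j}`` is the IVW estimate excluding SNP j.  Its null
    distribution is built by simulating, ``n_sim`` times,
    ``Gamma*_j ~ N(beta_{-j} gamma_j, se_Gamma_j)`` and
    ``gamma*_j ~ N(gamma_j, se_gamma_j)`` and recomputing the statistic;
    per-SNP p-values come from each SNP's own residual contribution, with
    outliers declared at Bonferroni-adjusted ``outlier_alpha``.  When
    outliers exist the corrected estimate is IVW on the remainder.
    """
    gamma, gse, Gamma, Gse, ids = _arrays(instruments)
    j = len(gamma)
    if j < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 instruments, got {j}")
    if n_sim < 500:
        raise ValueError("n_sim must be >= 500")
    if np.any(gamma == 0):
        raise ValueError("exposure beta of 0 present")

    def loo_beta(gam, Gam):
        w = gam**2 / Gse**2
        r = Gam / gam
        sw = w.sum(axis=-1, keepdims=True)
        swr = (w * r).sum(axis=-1, keepdims=True)
        return (swr - w * r) / (sw - w)

    b_loo = loo_beta(gamma[None, :], Gamma[None, :])[0]
    contrib_obs = ((Gamma - b_loo * gamma) / Gse) ** 2
    rss_obs = float(contrib_obs.sum())

    rng = np.random.default_rng(seed)
    gs = rng.normal(gamma, gse, size=(n_sim, j))
    Gs = rng.normal(b_loo * gamma, Gse, size=(n_sim, j))
    b_loo_sim = loo_beta(gs, Gs)
    contrib_sim = ((Gs - b_loo_sim * gs) / Gse) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    per_snp_p = (1 + (contrib_sim >= contrib_obs).sum(axis=0)) / (n_sim + 1)
    thresh = outlier_alpha / j
    outliers = tuple(int(i) for i in np.where(per_snp_p < thresh)[0])
    if len(outliers) == j:
        raise ValueError("all instruments flagged as outliers; no corrected estimate possible")
    corrected = None
    if outliers:
        seq = [h for h in (instruments.instruments if isinstance(instruments, InstrumentSet)
                           else instruments) if h.usable]
        keep = [h for i, h in enumerate(seq) if i not in outliers]
        corrected = ivw_fixed(keep)
        corrected = MrResult(**{**corrected.__dict__, "method": "presso_corrected"})
    return PressoReport(
        global_rss=rss_obs, global_p=global_p, n_sim=n_sim,
        per_snp_p=tuple(float(p) for p in per_snp_p),
        outlier_indices=outliers, outlier_ids=tuple(ids[i] for i in outliers),
        corrected=corrected,
    )


def run_mr_suite(instruments, seed: int = 0, n_boot: int = 1000,
                 presso_n_sim: int = 1000) -> dict:
    """Run every applicable estimator on one instrument set.

    Returns a dict with keys among ``ivw``, ``egger``, ``weighted_median``,
    ``leave_one_out``, ``presso`` depending on how many instruments are
    available.
    """
    gamma, *_ = _arrays(instruments)
    j = len(gamma)
    out: dict = {"ivw": ivw_fixed(instruments)}
    if j >= 2:
        out["weighted_median"] = weighted_median(instruments, n_boot=n_boot, seed=seed)
        out["leave_one_out"] = leave_one_out(instruments)
    if j >= 3:
        out["egger"] = egger(instruments)
    if j >= 4:
        out["presso"] = mr_presso(instruments, n_sim=presso_n_sim, seed=seed + 1)
    return out
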