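"""Repeated-simulation studies: estimator calibration, robustness, and detection power.

Each study repeatedly simulates a two-sample dataset through the full
pipeline path (simulate -> GWAS -> instrument selection -> harmonisation ->
estimation) and summarises how the estimators behave against the known
truth.  These functions are the machinery behind the package's calibration
claims and are deliberately part of the public surface so the claims can be
re-derived at any problem size.

Default problem sizes are chosen to mirror the study each scenario emulates
(exposure GWAS of tens of thousands, sepsis case-control GWAS of hundreds
of thousands at ~2.5% prevalence) while remaining runnable on one CPU in a
few minutes; see docs/methods.md for the reasoning behind each default.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import mr
from .simulate import SimulationParams, make_two_sample_dataset, simulate_cohort, single_snp_gwas
from .strata import compute_prs, haemoglobin_strata, residualise, strata_logistic, stratify
from .summary import harmonise, select_instruments


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _harmonised_dataset(params: SimulationParams, p_threshold: float = 5e-8):
    """Full summary-level path: simulate, select by p, harmonise; returns instruments."""
    exp_stats, out_stats, truth = make_two_sample_dataset(params)
    sel = select_instruments(exp_stats, p_threshold=p_threshold)
    return [h for h in harmonise(sel.snps, out_stats) if h.usable], truth


def ivw_calibration_study(
    n_reps: int = 200,
    seed: int = 0,
    theta: float = 0.15,
    n_snps: int = 25,
    n_per_sample: int = 50_000,
) -> dict:
    """Bias and 95% CI coverage of fixed-effects IVW under no pleiotropy.

    Returns mean estimate, bias, empirical coverage of the nominal 95% CI,
    and the Monte-Carlo SE of the bias.
    """
    base = SimulationParams(
        n_exposure_sample=n_per_sample, n_outcome_sample=n_per_sample,
        n_snps=n_snps, causal_effect_theta=theta, pleiotropy_mode="none",
    )
    estimates, covered = [], 0
    for s in _rep_seeds(seed, n_reps):
        insts, _ = _harmonised_dataset(replace(base, seed=s))
        res = mr.ivw_fixed(insts)
        estimates.append(res.beta)
        if res.ci_low <= theta <= res.ci_high:
            covered += 1
    est = np.array(estimates)
    return {
        "theta": theta,
        "n_reps": n_reps,
        "mean_beta": float(est.mean()),
        "bias": float(est.mean() - theta),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
    }


def egger_pleiotropy_study(
    n_reps: int = 100,
    seed: int = 1,
    scale: float = 0.02,
    n_snps: int = 25,
    n_per_sample: int = 50_000,
) -> dict:
    """Recovery of a directional pleiotropic mean by the MR-Egger intercept.

    Directional pleiotropy delta_j ~ N(scale, (scale/2)^2) satisfies InSIDE
    by construction, so the mean Egger intercept over replicates should sit
    within Monte-Carlo error of the mean realised delta.
    """
    base = SimulationParams(
        n_exposure_sample=n_per_sample, n_outcome_sample=n_per_sample,
        n_snps=n_snps, pleiotropy_mode="directional", pleiotropy_scale=scale,
    )
    intercepts, delta_bars = [], []
    for s in _rep_seeds(seed, n_reps):
        insts, truth = _harmonised_dataset(replace(base, seed=s))
        res = mr.egger(insts)
        intercepts.append(res.intercept)
        # the estimand is the mean direct effect per exposure-increasing allele
        delta_bars.append(float((np.sign(truth.gamma) * truth.delta).mean()))
    ic = np.array(intercepts)
    return {
        "n_reps": n_reps,
        "delta_bar_true": float(np.mean(delta_bars)),
        "mean_intercept": float(ic.mean()),
        "se_mean_intercept": float(ic.std(ddof=1) / np.sqrt(n_reps)),
    }


def median_robustness_study(
    n_reps: int = 100,
    seed: int = 2,
    theta: float = 0.15,
    n_snps: int = 10,
    n_invalid: int = 3,
    pleiotropy_scale: float = 0.15,
    n_exposure: int = 50_000,
    n_outcome: int = 200_000,
) -> dict:
    """Weighted median vs IVW with 30% invalid (directionally pleiotropic) instruments.

    Instruments invalid through a common-direction direct effect bias IVW in
    proportion to their weight share; the weighted median stays near theta
    while fewer than half the weight is invalid.  The outcome sample is
    sized like a population case-control GWAS so per-variant ratio noise is
    small relative to the contamination.
    """
    base = SimulationParams(
        n_exposure_sample=n_exposure, n_outcome_sample=n_outcome,
        n_snps=n_snps, causal_effect_theta=theta,
        pleiotropy_mode="outlier", n_outliers=n_invalid,
        pleiotropy_scale=pleiotropy_scale,
    )
    wm, wm_se, ivw, ivw_se = [], [], [], []
    for s in _rep_seeds(seed, n_reps):
        insts, _ = _harmonised_dataset(replace(base, seed=s))
        r_wm = mr.weighted_median(insts, seed=s)
        r_ivw = mr.ivw_fixed(insts)
        wm.append(r_wm.beta)
        wm_se.append(r_wm.se)
        ivw.append(r_ivw.beta)
        ivw_se.append(r_ivw.se)
    return {
        "theta": theta,
        "n_reps": n_reps,
        "invalid_fraction": n_invalid / n_snps,
        "mean_wm": float(np.mean(wm)),
        "mean_wm_se": float(np.mean(wm_se)),
        "mean_ivw": float(np.mean(ivw)),
        "mean_ivw_se": float(np.mean(ivw_se)),
        "wm_bias": float(np.mean(wm) - theta),
        "ivw_bias": float(np.mean(ivw) - theta),
    }


def presso_study(
    n_reps: int = 50,
    seed: int = 3,
    theta: float = 0.15,
    n_snps: int = 25,
    outlier_scale: float = 0.5,
    n_per_sample: int = 50_000,
    n_sim: int = 1000,
) -> dict:
    """MR-PRESSO specificity (clean data) and sensitivity (one planted outlier).

    Reports the fraction of clean replicates with global p > 0.05, the
    fraction of outlier replicates where the planted SNP is flagged, and the
    mean absolute error of the raw vs outlier-corrected IVW estimate among
    flagged replicates.  The planted direct effect must be large relative to
    the *largest* per-variant outcome SE (low-frequency instruments have the
    noisiest outcome effects), hence the default scale of 0.5 log-odds.
    """
    clean = SimulationParams(
        n_exposure_sample=n_per_sample, n_outcome_sample=n_per_sample,
        n_snps=n_snps, causal_effect_theta=theta, pleiotropy_mode="none",
    )
    planted = replace(clean, pleiotropy_mode="outlier", n_outliers=1,
                      pleiotropy_scale=outlier_scale)
    clean_ok = 0
    for s in _rep_seeds(seed, n_reps):
        insts, _ = _harmonised_dataset(replace(clean, seed=s))
        rep = mr.mr_presso(insts, n_sim=n_sim, seed=s)
        if rep.global_p > 0.05:
            clean_ok += 1
    flagged = 0
    raw_err, corr_err = [], []
    for s in _rep_seeds(seed + 1, n_reps):
        insts, truth = _harmonised_dataset(replace(planted, seed=s))
        rep = mr.mr_presso(insts, n_sim=n_sim, seed=s)
        planted_id = f"snp{truth.outlier_indices[0] + 1:04d}"
        if planted_id in rep.outlier_ids:
            flagged += 1
        if rep.corrected is not None:
            raw_err.append(abs(mr.ivw_fixed(insts).beta - theta))
            corr_err.append(abs(rep.corrected.beta - theta))
    return {
        "n_reps": n_reps,
        "clean_global_p_gt_05": clean_ok / n_reps,
        "outlier_detection_rate": flagged / n_reps,
        "mean_abs_err_raw": float(np.mean(raw_err)) if raw_err else None,
        "mean_abs_err_corrected": float(np.mean(corr_err)) if corr_err else None,
    }


def strata_ordering_study(
    n_reps: int = 100,
    seed: int = 4,
    theta_anaemic: float = 0.45,
    theta_normal: float = 0.15,
    n_snps: int = 25,
    n_sample: int = 50_000,
) -> dict:
    """Does residual-stratified PRS analysis recover a stronger anaemic-stratum effect?

    Each replicate simulates a cohort whose causal effect of the exposure on
    sepsis is larger in anaemic individuals, builds the PRS from the true
    per-SNP exposure weights, residualises haemoglobin on the PRS, stratifies
    at the clinical cut-offs, and compares the per-stratum log-ORs.  Reports
    the fraction of replicates with the correct ordering and the mean
    raw-vs-residualised haemoglobin correlation.
    """
    base = SimulationParams(
        n_outcome_sample=n_sample, n_snps=n_snps, pleiotropy_mode="none",
    )
    correct = 0
    corrs = []
    defs = haemoglobin_strata()
    for s in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort(replace(base, seed=s), "outcome",
                                 theta_by_anaemia=(theta_anaemic, theta_normal))
        weights = dict(zip(cohort.snp_ids, cohort.truth.gamma))
        prs = compute_prs(cohort.dosages, cohort.snp_ids, weights)
        hb_adj, diag = residualise(cohort.haemoglobin, prs)
        corrs.append(diag["corr_raw_adjusted"])
        labels = stratify(hb_adj, defs, sex=cohort.sex_label)
        results = {r.name: r for r in strata_logistic(prs, cohort.sepsis, labels,
                                                      order=[d.name for d in defs])}
        ra, rn = results["anaemic"], results["non_anaemic"]
        if ra.log_or is not None and rn.log_or is not None and ra.log_or > rn.log_or:
            correct += 1
    return {
        "n_reps": n_reps,
        "ordering_rate": correct / n_reps,
        "mean_corr_raw_residualised": float(np.mean(corrs)),
        "theta_anaemic": theta_anaemic,
        "theta_normal": theta_normal,
    }
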