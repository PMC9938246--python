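"""Synthetic cohorts and two-sample GWAS summary statistics with known truth.

The generator emulates the data-generating process assumed by a two-sample
Mendelian-randomisation study of iron biomarkers and sepsis:

* genotypes ``g_ij ~ Binomial(2, f_j)`` at independent variants;
* a standardised exposure ``X = sum_j gamma_j (g_j - 2 f_j) + eps`` whose
  genetic component explains a configurable fraction (heritability /
  instrument R^2) of variance;
* a binary sepsis outcome ``Bernoulli(logistic(alpha + theta X + sum_j
  delta_j g_j))`` with the intercept solved so the marginal case fraction
  matches a configured prevalence (~2.5% mirrors a population sepsis
  cohort), and ``delta_j`` injecting horizontal pleiotropy in balanced,
  directional or single-outlier patterns;
* haemoglobin with sex-specific means and a small genetic loading via the
  exposure, and log-normal ferritin correlated with the exposure.

Exposure and outcome samples are drawn from disjoint random substreams of a
single seed, so the two GWAS never share individuals while sharing the same
per-SNP truth — the defining feature of the two-sample design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .summary import SnpAssociation

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "outlier")


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of one synthetic two-sample study.

    ``exposure_heritability`` is the variance in the exposure explained by
    the simulated instruments jointly (the instrument R^2, e.g. 0.20);
    ``causal_effect_theta`` is the true log-odds of sepsis per SD exposure;
    ``hb_loading_lambda`` is in g/L per SD exposure; ``ferritin_loading`` is
    the correlation of log-ferritin with the exposure.  The seed fully
    determines all output.
    """

    n_exposure_sample: int = 50_000
    n_outcome_sample: int = 50_000
    n_snps: int = 25
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    exposure_heritability: float = 0.20
    causal_effect_theta: float = 0.15
    outcome_prevalence: float = 0.025
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.0
    n_outliers: int = 1
    hb_loading_lambda: float = 1.0
    ferritin_log_mean: float = 4.5
    ferritin_log_sd: float = 1.0
    ferritin_loading: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("allele_freq_range must lie within (0, 0.5]")
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        for name in ("exposure_heritability", "outcome_prevalence"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if self.pleiotropy_mode == "outlier" and not (0 < self.n_outliers <= self.n_snps):
            raise ValueError("n_outliers must lie in [1, n_snps] for outlier pleiotropy")
        if not (-1 < self.ferritin_loading < 1):
            raise ValueError("ferritin_loading must lie in (-1, 1)")
        for name in ("n_exposure_sample", "n_outcome_sample"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


@dataclass(frozen=True)
class GeneticTruth:
    """Per-SNP generating values shared by both samples of one study."""

    snp_ids: tuple[str, ...]
    effect_allele: tuple[str, ...]
    other_allele: tuple[str, ...]
    freq: np.ndarray            # effect-allele frequencies f_j
    gamma: np.ndarray           # true SNP -> exposure effects
    delta: np.ndarray           # direct (pleiotropic) SNP -> outcome effects
    outlier_indices: tuple[int, ...]


@dataclass
class SyntheticCohort:
    """Individual-level data for one sample, plus the generating truth."""

    dosages: np.ndarray         # individuals x snps, values in [0, 2]
    snp_ids: list[str]
    exposure: np.ndarray        # SD units, mean ~0, SD ~1
    haemoglobin: np.ndarray     # g/L
    ferritin: np.ndarray        # ug/L, strictly positive
    sex: np.ndarray             # 0 = female, 1 = male
    sepsis: np.ndarray          # 0/1
    params: SimulationParams
    truth: GeneticTruth
    alpha: float                # solved outcome-model intercept

    @property
    def n(self) -> int:
        return len(self.exposure)

    @property
    def sex_label(self) -> np.ndarray:
        return np.where(self.sex == 1, "male", "female")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "sepsis", self.sepsis)
        df.insert(0, "ferritin", self.ferritin)
        df.insert(0, "haemoglobin", self.haemoglobin)
        df.insert(0, "sex", self.sex)
        df.insert(0, "exposure", self.exposure)
        return df


def _rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def make_truth(params: SimulationParams) -> GeneticTruth:
    """Draw the per-SNP truth (frequencies, effects, alleles) from its own substream."""
    params.validate()
    rng = _rng(params.seed, (0,))
    J = params.n_snps
    lo, hi = params.allele_freq_range
    freq = rng.uniform(lo, hi, J)
    var_g = 2.0 * freq * (1.0 - freq)
    # equal variance explained per SNP: gamma_j^2 * var(g_j) = h2 / J
    gamma = np.sqrt(params.exposure_heritability / (J * var_g))
    gamma *= rng.choice([-1.0, 1.0], J)

    # directional/outlier pleiotropy is defined relative to the
    # exposure-increasing allele (sign(gamma)), so that "directional" stays
    # directional after estimators orient instruments by exposure effect
    mode, scale = params.pleiotropy_mode, params.pleiotropy_scale
    delta = np.zeros(J)
    outliers: tuple[int, ...] = ()
    if mode == "balanced":
        delta = rng.normal(0.0, abs(scale), J)
    elif mode == "directional":
        delta = np.sign(gamma) * rng.normal(scale, abs(scale) / 2.0, J)
    elif mode == "outlier":
        idx = np.sort(rng.choice(J, size=params.n_outliers, replace=False))
        delta[idx] = np.sign(gamma[idx]) * scale
        outliers = tuple(int(i) for i in idx)

    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), J)
    eas = tuple(_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx)
    oas = tuple(_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx)
    ids = tuple(f"snp{j + 1:04d}" for j in range(J))
    return GeneticTruth(ids, eas, oas, freq, gamma, delta, outliers)


def _solve_intercept(eta: np.ndarray, prevalence: float, tol: float = 1e-6,
                     max_iter: int = 200) -> float:
    """Bisect alpha so that mean(expit(alpha + eta)) hits the target prevalence."""
    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + eta))) - prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"outcome_prevalence={prevalence} unattainable for the simulated linear predictor"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v) < tol:
            return mid
        if v < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sepsis_from_eta(eta, prevalence, rng):
    alpha = _solve_intercept(eta, prevalence)
    p = expit(alpha + eta)
    return rng.binomial(1, p).astype(np.int8), alpha


def simulate_cohort(
    params: SimulationParams,
    which_sample: Literal["exposure", "outcome"],
    replicate: int = 0,
    theta_by_anaemia: tuple[float, float] | None = None,
) -> SyntheticCohort:
    """Simulate one individual-level sample of the two-sample design.

    ``which_sample`` selects a disjoint random substream so exposure and
    outcome cohorts never overlap.  ``replicate`` selects a further
    independent draw from the same truth (used e.g. for a second outcome
    cohort in a cross-cohort meta-analysis).

    ``theta_by_anaemia``, when given as ``(theta_anaemic, theta_normal)``,
    replaces the single causal effect with an effect modified by anaemia
    status (haemoglobin below 125 g/L for women, 135 g/L for men) — the
    regime the residual-stratified PRS analysis is designed to detect.
    """
    if which_sample not in ("exposure", "outcome"):
        raise ValueError("which_sample must be 'exposure' or 'outcome'")
    truth = make_truth(params)
    key = (1 if which_sample == "exposure" else 2, replicate)
    rng = _rng(params.seed, key)
    n = params.n_exposure_sample if which_sample == "exposure" else params.n_outcome_sample
    J = params.n_snps

    g = rng.binomial(2, truth.freq, size=(n, J)).astype(np.float64)
    gc = g - 2.0 * truth.freq
    h2 = params.exposure_heritability
    x = gc @ truth.gamma + rng.normal(0.0, math.sqrt(1.0 - h2), n)

    sex = rng.integers(0, 2, n).astype(np.int8)  # 1 = male
    hb = (
        np.where(sex == 1, 151.0, 135.0)
        + params.hb_loading_lambda * x
        + rng.normal(0.0, 10.0, n)
    )

    rho = params.ferritin_loading
    z = rng.normal(size=n)
    log_ferr = params.ferritin_log_mean + params.ferritin_log_sd * (
        rho * x + math.sqrt(1.0 - rho**2) * z
    )
    ferritin = np.exp(log_ferr)

    if theta_by_anaemia is None:
        eta = params.causal_effect_theta * x + g @ truth.delta
    else:
        th_a, th_n = theta_by_anaemia
        anaemic = hb < np.where(sex == 1, 135.0, 125.0)
        eta = np.where(anaemic, th_a, th_n) * x + g @ truth.delta
    sepsis, alpha = _sepsis_from_eta(eta, params.outcome_prevalence, rng)

    return SyntheticCohort(
        dosages=g, snp_ids=list(truth.snp_ids), exposure=x, haemoglobin=hb,
        ferritin=ferritin, sex=sex, sepsis=sepsis, params=params, truth=truth,
        alpha=alpha,
    )


def _batch_univariable_logistic(g: np.ndarray, y: np.ndarray, max_iter: int = 40,
                                tol: float = 1e-10):
    """Vectorised per-SNP logistic regression of y on [1, g_j], one fit per column.

    Newton-Raphson on J independent 2-parameter problems simultaneously.
    Returns (beta, se, converged_mask); monomorphic columns come back with
    se = inf and converged False.
    """
    n, J = g.shape
    y = y.astype(np.float64)
    mono = g.std(axis=0) == 0
    b0 = np.full(J, logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b1 = np.zeros(J)
    active = ~mono
    for _ in range(max_iter):
        eta = b0 + g * b1
        p = expit(eta)
        w = p * (1.0 - p)
        r = y[:, None] - p
        u0 = r.sum(axis=0)
        u1 = (g * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * g).sum(axis=0)
        i11 = (w * g * g).sum(axis=0)
        det = i00 * i11 - i01 * i01
        det = np.where(det <= 0, np.nan, det)
        d0 = (i11 * u0 - i01 * u1) / det
        d1 = (-i01 * u0 + i00 * u1) / det
        d0 = np.where(active, d0, 0.0)
        d1 = np.where(active, d1, 0.0)
        b0 += d0
        b1 += d1
        step = np.maximum(np.abs(d0), np.abs(d1))
        if np.nanmax(np.where(active, step, 0.0)) < tol:
            break
    eta = b0 + g * b1
    p = expit(eta)
    w = p * (1.0 - p)
    i00 = w.sum(axis=0)
    i01 = (w * g).sum(axis=0)
    i11 = (w * g * g).sum(axis=0)
    det = i00 * i11 - i01 * i01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(i00 / det)
    se1 = np.where(mono | ~np.isfinite(se1), np.inf, se1)
    b1 = np.where(mono, 0.0, b1)
    return b1, se1, ~mono


def single_snp_gwas(
    cohort: SyntheticCohort,
    trait: Literal["exposure_linear", "sepsis_logistic"],
) -> list[SnpAssociation]:
    """Per-SNP univariable GWAS of the cohort, returning summary associations.

    Linear regression for the continuous exposure, logistic for sepsis.  The
    effect allele is the counted (dosage) allele.  Monomorphic SNPs are
    reported with infinite SE and a ``monomorphic`` note rather than silent
    NaNs.
    """
    g = cohort.dosages
    n, J = g.shape
    t = cohort.truth
    eaf = g.mean(axis=0) / 2.0

    if trait == "exposure_linear":
        y = cohort.exposure
        gm = g.mean(axis=0)
        gv = ((g - gm) ** 2).sum(axis=0)
        mono = gv == 0
        ym = y.mean()
        sxy = ((g - gm) * (y - ym)[:, None]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / gv
            rss = ((y - ym) ** 2).sum() - beta * sxy
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 / gv)
        ok = ~mono
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.abs(beta / se)
        pval = 2.0 * stats.t.sf(tval, df=n - 2)
    elif trait == "sepsis_logistic":
        beta, se, ok = _batch_univariable_logistic(g, cohort.sepsis)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(beta / se)
        pval = 2.0 * stats.norm.sf(z)
    else:
        raise ValueError(f"unknown trait {trait!r}")

    out = []
    for j in range(J):
        if ok[j]:
            rec = SnpAssociation(
                t.snp_ids[j], t.effect_allele[j], t.other_allele[j],
                eaf=float(eaf[j]) if 0 < eaf[j] < 1 else None,
                beta=float(beta[j]), se=float(se[j]),
                pval=float(min(max(pval[j], 5e-324), 1.0)), n=n,
            )
        else:
            rec = SnpAssociation(
                t.snp_ids[j], t.effect_allele[j], t.other_allele[j],
                eaf=None, beta=0.0, se=math.inf, pval=1.0, n=n, note="monomorphic",
            )
        out.append(rec)
    return out


def make_two_sample_dataset(
    params: SimulationParams, outcome_replicate: int = 0
) -> tuple[list[SnpAssociation], list[SnpAssociation], GeneticTruth]:
    """Simulate disjoint exposure and outcome cohorts and their GWAS tables."""
    exp_cohort = simulate_cohort(params, "exposure")
    out_cohort = simulate_cohort(params, "outcome", replicate=outcome_replicate)
    exp_stats = single_snp_gwas(exp_cohort, "exposure_linear")
    out_stats = single_snp_gwas(out_cohort, "sepsis_logistic")
    return exp_stats, out_stats, exp_cohort.truth


@dataclass
class LdBlock:
    """A block of correlated dosages plus its empirical r^2 matrix."""

    dosages: np.ndarray
    snp_ids: list[str]
    r2: np.ndarray
    warning: str | None = None


def simulate_ld_block(
    n_individuals: int,
    target_r: float,
    n_snps: int,
    seed: int = 0,
    freq: float = 0.3,
) -> LdBlock:
    """Simulate dosages with pairwise correlation ``target_r`` via a shared haplotype.

    Each haplotype allele copies a shared "core" allele with probability
    sqrt(|target_r|) and is drawn independently otherwise, which gives
    pairwise allele (and dosage) correlation of exactly |target_r| in
    expectation.  Negative targets are only representable for 2-SNP blocks
    (an equicorrelated negative matrix is not positive semi-definite beyond
    that) and are realised by complementing the second SNP's copied allele.
    """
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    if target_r < 0 and n_snps > 2:
        raise ValueError("negative target_r only supported for n_snps <= 2")
    rng = np.random.default_rng(seed)
    p_copy = math.sqrt(abs(target_r))
    dosages = np.zeros((n_individuals, n_snps))
    for _hap in range(2):
        core = (rng.random(n_individuals) < freq).astype(np.float64)
        copy = rng.random((n_individuals, n_snps)) < p_copy
        indep = (rng.random((n_individuals, n_snps)) < freq).astype(np.float64)
        source = core[:, None] * np.ones(n_snps)
        if target_r < 0:
            source[:, 1] = 1.0 - core
        dosages += np.where(copy, source, indep)
    if n_snps == 1:
        r2 = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore"):
            r2 = np.corrcoef(dosages.T) ** 2
        np.fill_diagonal(r2, 1.0)
    warning = None
    if n_individuals < 10_000:
        warning = f"n={n_individuals} < 10000: empirical r2 estimate may be unstable"
    ids = [f"ld{j + 1:03d}" for j in range(n_snps)]
    return LdBlock(dosages=dosages, snp_ids=ids, r2=r2, warning=warning)


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write the individual-level table (phenotypes + dosage columns) as TSV."""
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def simulate_observational_cohort(
    n: int,
    seed: int = 0,
    log_or_per_100: float = 0.05,
    prevalence: float = 0.033,
    ferritin_log_mean: float = 4.5,
    ferritin_log_sd: float = 1.0,
    risk: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate an observational ferritin cohort with a known dose-response.

    By default sepsis log-odds rise linearly at ``log_or_per_100`` per
    100 ug/L of ferritin; passing ``risk`` (a callable mapping the ferritin
    vector to a log-odds offset) overrides the shape, e.g. to plant a
    U-shaped curve for spline-recovery tests.  Age, sex, and smoking are
    included as covariates with mild confounding through age.
    """
    rng = np.random.default_rng(seed)
    ferritin = np.exp(rng.normal(ferritin_log_mean, ferritin_log_sd, n))
    age = rng.uniform(40, 70, n)
    sex = rng.integers(0, 2, n)
    smoker = rng.binomial(1, 0.1, n)
    if risk is None:
        eta = log_or_per_100 * ferritin / 100.0
    else:
        eta = np.asarray(risk(ferritin), dtype=float)
    eta = eta + 0.02 * (age - 55.0)
    alpha = _solve_intercept(eta, prevalence)
    sepsis = rng.binomial(1, expit(alpha + eta))
    return pd.DataFrame(
        {"ferritin": ferritin, "age": age, "sex": sex, "smoker": smoker, "sepsis": sepsis}
    )
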