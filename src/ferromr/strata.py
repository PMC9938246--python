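"""Polygenic scores, residual-based stratification, and per-stratum associations.

A weighted allelic polygenic risk score (PRS) ``S_i = sum_j w_j g_ij`` is
built from the same variants and exposure weights as the MR instruments
and standardised to mean 0, SD 1, so per-stratum odds ratios are per SD of
the PRS.

Stratifying directly on a biomarker the PRS influences (haemoglobin,
ferritin) would condition on a collider.  Instead the biomarker is
regressed on the PRS by OLS and the grand mean plus residuals — the
non-genetic component, still in clinical units so cut-offs like 125 g/L or
50 ug/L stay meaningful — defines the strata.  When the genetic loading is
small the residualised values correlate > 0.99 with the raw values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr import Z95
from .observational import SeparationError, fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class PrsVector:
    """A standardised per-individual polygenic score and its provenance."""

    score: np.ndarray           # mean 0, SD 1
    weights: dict[str, float]   # per-SNP exposure effect sizes used
    raw_mean: float
    raw_sd: float


@dataclass(frozen=True)
class StratumDefinition:
    """One stratum: a half-open/closed interval of a biomarker, optionally per sex.

    ``lower``/``upper`` may be scalars or mappings keyed by sex label
    (e.g. ``{"female": 125, "male": 135}``) for sex-specific cut-offs.
    """

    name: str
    variable: str
    lower: float | Mapping[str, float] = -math.inf
    upper: float | Mapping[str, float] = math.inf
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    @property
    def sex_specific(self) -> bool:
        return isinstance(self.lower, Mapping) or isinstance(self.upper, Mapping)

    def _bounds(self, sex: np.ndarray | None, n: int):
        def expand(b):
            if isinstance(b, Mapping):
                if sex is None:
                    raise ValueError(f"stratum {self.name!r} is sex-specific but no sex given")
                return np.array([b[s] for s in sex], dtype=float)
            return np.full(n, b, dtype=float)

        return expand(self.lower), expand(self.upper)

    def mask(self, values: np.ndarray, sex: np.ndarray | None) -> np.ndarray:
        lo, hi = self._bounds(sex, len(values))
        above = values >= lo if self.lower_inclusive else values > lo
        below = values <= hi if self.upper_inclusive else values < hi
        return above & below


def haemoglobin_strata(female_cutoff: float = 125.0, male_cutoff: float = 135.0):
    """Anaemic / non-anaemic split at the NICE haemoglobin cut-offs (g/L)."""
    cut = {"female": female_cutoff, "male": male_cutoff}
    return [
        StratumDefinition("anaemic", "haemoglobin", upper=cut, upper_inclusive=False),
        StratumDefinition("non_anaemic", "haemoglobin", lower=cut,
                          lower_inclusive=True, upper_inclusive=True),
    ]


def ferritin_strata(low: float = 50.0, high: float = 450.0):
    """Iron deficient (< low), normal [low, high], high (> high), in ug/L."""
    return [
        StratumDefinition("low", "ferritin", upper=low, upper_inclusive=False),
        StratumDefinition("normal", "ferritin", lower=low, upper=high,
                          lower_inclusive=True, upper_inclusive=True),
        StratumDefinition("high", "ferritin", lower=high, lower_inclusive=False,
                          upper_inclusive=True),
    ]


@dataclass(frozen=True)
class StratumResult:
    """Per-stratum logistic association of sepsis with the PRS (OR per SD)."""

    name: str
    n: int
    cases: int
    or_per_sd: float | None
    ci_low: float | None
    ci_high: float | None
    pval: float | None
    log_or: float | None = None
    se: float | None = None
    flag: str | None = None


def compute_prs(dosages, snp_ids: Sequence[str], weights: Mapping[str, float]) -> PrsVector:
    """Weighted allelic score over the dosage columns, standardised to SD units.

    Every weight's SNP must be present among ``snp_ids``; unmatched IDs are
    listed in the error.  A zero-variance raw score cannot be standardised
    and is rejected.
    """
    if isinstance(dosages, pd.DataFrame):
        snp_ids = list(dosages.columns)
        dosages = dosages.to_numpy(dtype=float)
    index = {s: i for i, s in enumerate(snp_ids)}
    missing = [s for s in weights if s not in index]
    if missing:
        raise ValueError(f"weights refer to SNPs absent from dosages: {missing}")
    order = sorted(weights)
    w = np.array([weights[s] for s in order])
    g = dosages[:, [index[s] for s in order]]
    raw = g @ w
    mu, sd = float(raw.mean()), float(raw.std())
    if sd == 0:
        raise ValueError("polygenic score has zero variance; cannot standardise")
    return PrsVector(score=(raw - mu) / sd, weights={s: float(weights[s]) for s in order},
                     raw_mean=mu, raw_sd=sd)


def residualise(values, prs: PrsVector, direction: str = "biomarker_on_prs"):
    """Remove the genetic (PRS) component of a biomarker, keeping clinical units.

    Default OLS of biomarker on PRS; output = grand mean + residuals, so
    the result is exactly orthogonal to the PRS but keeps the original
    clinical scale (absolute cut-offs stay meaningful).  The alternative
    reading ``direction="prs_on_biomarker"`` regresses the PRS on the
    biomarker and returns the residualised *PRS* (grand mean + residuals,
    in SD units) — provided for comparison, with no claim about which
    reading is intended by convention.

    Returns (adjusted values, diagnostics) with the fitted slope and the
    correlation between raw and adjusted values of the regression response.
    """
    y = np.asarray(values, dtype=float)
    if y.std() == 0:
        raise ValueError("biomarker has zero variance; nothing to residualise")
    s = prs.score
    if len(y) != len(s):
        raise ValueError("biomarker and PRS lengths differ")
    if direction == "prs_on_biomarker":
        y, s = s, y  # swap response and regressor; residualise the PRS instead
    elif direction != "biomarker_on_prs":
        raise ValueError(f"unknown direction {direction!r}")
    b = float(np.dot(s - s.mean(), y - y.mean()) / np.dot(s - s.mean(), s - s.mean()))
    fitted = y.mean() + b * (s - s.mean())
    adjusted = y.mean() + (y - fitted)
    corr = float(np.corrcoef(y, adjusted)[0, 1]) if np.std(adjusted) > 0 else math.nan
    return adjusted, {"slope": b, "corr_raw_adjusted": corr, "direction": direction}


def stratify(values, definitions: Sequence[StratumDefinition], sex=None) -> np.ndarray:
    """Assign each individual to exactly one stratum; definitions must be exhaustive."""
    values = np.asarray(values, dtype=float)
    sex = None if sex is None else np.asarray(sex)
    masks = np.stack([d.mask(values, sex) for d in definitions])
    hits = masks.sum(axis=0)
    if np.any(hits == 0):
        i = int(np.argmax(hits == 0))
        raise ValueError(f"value {values[i]!r} falls outside all strata (definitions not exhaustive)")
    if np.any(hits > 1):
        i = int(np.argmax(hits > 1))
        raise ValueError(f"value {values[i]!r} matches multiple strata (definitions overlap)")
    labels = np.empty(len(values), dtype=object)
    for d, m in zip(definitions, masks):
        labels[m] = d.name
    return labels


def strata_logistic(prs: PrsVector, outcome, labels,
                    order: Sequence[str] | None = None) -> list[StratumResult]:
    """Logistic regression of the outcome on the (globally scaled) PRS per stratum.

    The PRS keeps its cohort-wide standardisation — it is *not* re-scaled
    within strata, so ORs are comparable across strata.  Strata with no
    cases, no controls, or separation are flagged, never silently dropped.
    """
    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(labels)
    names = list(order) if order is not None else list(dict.fromkeys(labels))
    out: list[StratumResult] = []
    for name in names:
        m = labels == name
        n, cases = int(m.sum()), int(y[m].sum())
        if n == 0 or cases == 0 or cases == n:
            flag = "empty" if n == 0 else ("no_cases" if cases == 0 else "no_controls")
            out.append(StratumResult(name, n, cases, None, None, None, None, flag=flag))
            continue
        X = np.column_stack([np.ones(n), prs.score[m]])
        try:
            fit = fit_logistic(X, y[m])
        except (SeparationError, RuntimeError) as exc:
            out.append(StratumResult(name, n, cases, None, None, None, None,
                                     flag=f"fit_failed: {exc}"))
            continue
        b, se = float(fit.params[1]), float(fit.bse[1])
        out.append(
            StratumResult(
                name, n, cases,
                or_per_sd=math.exp(b),
                ci_low=math.exp(b - Z95 * se), ci_high=math.exp(b + Z95 * se),
                pval=float(2.0 * stats.norm.sf(abs(b / se))),
                log_or=b, se=se,
            )
        )
    return out


def prs_covariate_scan(prs: PrsVector, covariates: pd.DataFrame,
                       kinds: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Associate each covariate with the PRS (linear or logistic by type).

    A re-implementation of a phenome-scan step as a plain regression scan:
    continuous covariates are regressed on the PRS by OLS; binary ones by
    logistic regression of the covariate on the PRS.  Constant covariates
    are skipped with a diagnostic row.  Returns a tidy table.
    """
    rows = []
    s = prs.score
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        uniq = np.unique(v[~np.isnan(v)])
        if len(uniq) < 2:
            rows.append({"covariate": name, "kind": "constant", "estimate": None,
                         "se": None, "ci_low": None, "ci_high": None, "pval": None,
                         "note": "constant covariate skipped"})
            continue
        kind = (kinds or {}).get(name) or ("binary" if len(uniq) == 2 else "continuous")
        ok = ~np.isnan(v)
        if kind == "binary":
            vb = (v[ok] == uniq.max()).astype(float)
            try:
                fit = fit_logistic(np.column_stack([np.ones(ok.sum()), s[ok]]), vb)
            except (SeparationError, RuntimeError) as exc:
                rows.append({"covariate": name, "kind": kind, "estimate": None, "se": None,
                             "ci_low": None, "ci_high": None, "pval": None,
                             "note": f"fit_failed: {exc}"})
                continue
            b, se = float(fit.params[1]), float(fit.bse[1])
        else:
            sc = s[ok] - s[ok].mean()
            vc = v[ok] - v[ok].mean()
            b = float(np.dot(sc, vc) / np.dot(sc, sc))
            resid = vc - b * sc
            dof = ok.sum() - 2
            se = float(np.sqrt((resid @ resid) / dof / np.dot(sc, sc)))
        rows.append({
            "covariate": name, "kind": kind, "estimate": b, "se": se,
            "ci_low": b - Z95 * se, "ci_high": b + Z95 * se,
            "pval": float(2.0 * stats.norm.sf(abs(b / se))), "note": None,
        })
    return pd.DataFrame(rows, columns=["covariate", "kind", "estimate", "se",
                                       "ci_low", "ci_high", "pval", "note"])
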