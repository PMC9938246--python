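"""Observational ferritin -> sepsis modelling: cohort rules, logistic fits, splines.

The observational arm asks whether the index ferritin level (the first test
recorded after recruitment, with implausible values above 10,000 ug/L
excluded) predicts a later sepsis admission.  Association is modelled two
ways: an adjusted logistic regression reported per 100 ug/L of ferritin,
and a restricted-cubic-spline logistic model whose dose-response curve is
expressed as OR(x) relative to a reference ferritin value.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mr import Z95

logger = logging.getLogger(__name__)

FERRITIN_MAX = 10_000.0
DEFAULT_KNOT_QUANTILES = (0.05, 0.275, 0.5, 0.725, 0.95)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, SEs, covariance, diagnostics."""

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    llf: float
    n: int

    def ci(self, i: int) -> tuple[float, float]:
        return self.params[i] - Z95 * self.bse[i], self.params[i] + Z95 * self.bse[i]

    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.params / self.bse))


class SeparationError(ValueError):
    """Complete or quasi-complete separation: the MLE does not exist."""


def fit_logistic(X, y, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Fit a logistic regression by Newton-Raphson (maximum likelihood).

    Requires a full-rank design.  Non-convergence raises with the iteration
    trace; separation raises :class:`SeparationError` rather than returning
    runaway coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome value")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
    except Exception as exc:  # statsmodels raises PerfectSeparationError or LinAlgError
        if "erfect" in type(exc).__name__ or "ingular" in str(exc):
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
        raise
    retvals = getattr(res, "mle_retvals", {})
    converged = bool(retvals.get("converged", True))
    n_iter = int(retvals.get("iterations", max_iter))
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(trace: {retvals})"
        )
    fitted = res.predict()
    if np.all((fitted > 1 - 1e-10) == (y == 1)) and np.all((fitted < 1e-10) == (y == 0)):
        raise SeparationError("fitted probabilities are all 0/1: complete separation")
    return LogisticFit(
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        converged=converged,
        n_iter=n_iter,
        llf=float(res.llf),
        n=len(y),
    )


def build_cohort(
    tests: pd.DataFrame,
    baseline: pd.DataFrame,
    ferritin_max: float = FERRITIN_MAX,
) -> pd.DataFrame:
    """Apply the cohort rules: index test per participant, extreme values excluded.

    ``tests`` needs columns (participant_id, date, ferritin); ``baseline``
    needs (participant_id, recruitment_date) plus any covariates.  The index
    ferritin is the first test dated strictly after recruitment; values above
    ``ferritin_max`` are excluded before index selection.  Exclusion counts
    are logged by rule and stored in ``result.attrs['exclusions']``.
    """
    for c in ("participant_id", "date", "ferritin"):
        if c not in tests.columns:
            raise ValueError(f"tests table missing column {c!r}")
    for c in ("participant_id", "recruitment_date"):
        if c not in baseline.columns:
            raise ValueError(f"baseline table missing column {c!r}")
    if baseline["participant_id"].duplicated().any():
        dups = baseline.loc[baseline["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participants in baseline table: {list(dups)[:5]}")

    excl = {}
    merged = tests.merge(baseline, on="participant_id", how="inner")
    excl["no_baseline"] = len(tests) - len(merged)
    extreme = merged["ferritin"] > ferritin_max
    excl[f"ferritin_gt_{ferritin_max:g}"] = int(extreme.sum())
    merged = merged[~extreme]
    pre = merged["date"] <= merged["recruitment_date"]
    excl["test_not_after_recruitment"] = int(pre.sum())
    merged = merged[~pre]
    merged = merged.sort_values(["participant_id", "date"], kind="mergesort")
    cohort = merged.drop_duplicates("participant_id", keep="first").reset_index(drop=True)
    excl["later_tests_same_participant"] = len(merged) - len(cohort)
    if cohort["participant_id"].duplicated().any():
        raise ValueError("duplicate participant after index-test filtering")
    logger.info("build_cohort: %d participants; exclusions %s", len(cohort), excl)
    cohort.attrs["exclusions"] = excl
    return cohort


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated power form, linear tails).

    With k strictly increasing knots ``t_1..t_k`` the basis has k-1 columns:
    the identity, plus for j = 1..k-2 the nonlinear term

        C_j(x) = [ (x-t_j)+^3
                   - (x-t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
                   + (x-t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

    which is zero below t_j and exactly linear beyond the boundary knots.
    """
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing and distinct")
    x = np.asarray(x, dtype=float)
    k = len(t)
    plus3 = lambda v: np.maximum(v, 0.0) ** 3
    denom = (t[-1] - t[0]) ** 2
    tail = t[-1] - t[-2]
    out = np.empty((len(x), k - 1))
    out[:, 0] = x
    for j in range(k - 2):
        out[:, j + 1] = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / tail
            + plus3(x - t[-1]) * (t[-2] - t[j]) / tail
        ) / denom
    return out


@dataclass
class SplineSpec:
    """Knot locations and the reference value against which ORs are expressed."""

    knots: np.ndarray
    reference: float

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")


@dataclass
class RcsLogisticModel:
    """A fitted spline logistic model plus what is needed to draw OR curves."""

    fit: LogisticFit
    spec: SplineSpec
    spline_cols: slice  # columns of the design holding the spline basis


def default_knots(x, quantiles: Sequence[float] = DEFAULT_KNOT_QUANTILES) -> np.ndarray:
    """Knots at conventional quantiles of the observed predictor (5-knot default)."""
    return np.quantile(np.asarray(x, dtype=float), quantiles)


def fit_rcs_logistic(
    x,
    y,
    knots=None,
    covariates=None,
    reference: float | None = None,
) -> RcsLogisticModel:
    """Fit logit(y) ~ rcs(x) [+ covariates]; reference defaults to median x."""
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = default_knots(x)
    basis = rcs_basis(x, knots)
    cols = [np.ones((len(x), 1)), basis]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = np.hstack(cols)
    fit = fit_logistic(X, y)
    ref = float(np.median(x)) if reference is None else float(reference)
    spec = SplineSpec(knots=np.asarray(knots, dtype=float), reference=ref)
    return RcsLogisticModel(fit=fit, spec=spec, spline_cols=slice(1, 1 + basis.shape[1]))


def spline_or_curve(model: RcsLogisticModel, grid, reference: float | None = None) -> pd.DataFrame:
    """OR(x) with pointwise 95% CI relative to the reference value.

    ``OR(x) = exp(eta(x) - eta(ref))`` uses only the spline coefficients
    (covariate terms cancel); the CI comes from the delta method on the
    coefficient covariance.  OR at the reference is exactly 1 with a
    zero-width interval.
    """
    spec = model.spec
    ref = spec.reference if reference is None else float(reference)
    if not (spec.knots[0] <= ref <= spec.knots[-1]):
        warnings.warn(
            f"reference {ref:g} lies outside the knot span "
            f"[{spec.knots[0]:g}, {spec.knots[-1]:g}]; curve is extrapolated",
            stacklevel=2,
        )
    grid = np.asarray(grid, dtype=float)
    d = rcs_basis(grid, spec.knots) - rcs_basis(np.array([ref]), spec.knots)
    b = model.fit.params[model.spline_cols]
    cov = model.fit.cov[model.spline_cols, model.spline_cols]
    eta = d @ b
    var = np.einsum("ij,jk,ik->i", d, cov, d)
    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "x": grid,
            "or": np.exp(eta),
            "ci_low": np.exp(eta - Z95 * se),
            "ci_high": np.exp(eta + Z95 * se),
        }
    )


def _encode_covariates(cohort: pd.DataFrame, covariates: Sequence[str]):
    """Numeric covariates pass through; categoricals one-hot with largest level as reference."""
    cols, names = [], []
    for c in covariates:
        s = cohort[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float)[:, None])
            names.append(c)
        else:
            levels = s.value_counts().index.tolist()
            for lv in sorted(map(str, levels[1:])):
                cols.append((s.astype(str) == lv).to_numpy(dtype=float)[:, None])
                names.append(f"{c}[{lv}]")
    if not cols:
        return np.empty((len(cohort), 0)), []
    return np.hstack(cols), names


def ferritin_linear_model(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    exclude_below: float | None = None,
) -> dict:
    """Adjusted logistic OR of sepsis per 100 ug/L of ferritin.

    ``exclude_below`` left-truncates the cohort (e.g. at 50 ug/L to drop
    likely iron deficiency) before fitting.
    """
    df = cohort
    if exclude_below is not None:
        df = df[df["ferritin"] >= exclude_below]
        if df.empty:
            raise ValueError(f"empty cohort after excluding ferritin < {exclude_below}")
    covs, names = _encode_covariates(df, covariates)
    X = np.hstack([np.ones((len(df), 1)), (df["ferritin"].to_numpy(dtype=float) / 100.0)[:, None], covs])
    fit = fit_logistic(X, df["sepsis"].to_numpy(dtype=float))
    beta, se = fit.params[1], fit.bse[1]
    return {
        "or_per_100": math.exp(beta),
        "ci_low": math.exp(beta - Z95 * se),
        "ci_high": math.exp(beta + Z95 * se),
        "log_or": float(beta),
        "se": float(se),
        "pval": float(2.0 * stats.norm.sf(abs(beta / se))),
        "n": len(df),
        "covariates": ["ferritin_per_100"] + names,
        "fit": fit,
    }
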