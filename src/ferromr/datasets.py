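"""Published reference numbers used as worked-example inputs.

Per-cohort IVW MR odds ratios (95% CI) of each iron biomarker on sepsis,
as reported for the FinnGen and UK Biobank outcome cohorts, plus the
published combined rows and outcome-cohort case counts.  These printed
2-decimal values are inputs to the meta-analysis recombination example;
the residual rounding error of recombining them is ~0.005 on the OR
scale.  The published combined TSAT row is internally inconsistent across
report locations (1.09 vs 1.11), so no equality is asserted for TSAT
anywhere — the recombined value is simply reported.
"""

from __future__ import annotations

from .meta import CohortEstimate, MetaResult, fixed_effects_meta

#: biomarker -> cohort -> (OR, 95% CI lower, upper)
PER_COHORT_IVW: dict[str, dict[str, tuple[float, float, float]]] = {
    "tsat": {"FinnGen": (1.05, 0.94, 1.16), "UK Biobank": (1.17, 1.09, 1.24)},
    "iron": {"FinnGen": (1.24, 1.03, 1.45), "UK Biobank": (1.13, 1.03, 1.23)},
    "tibc": {"FinnGen": (0.94, 0.84, 1.04), "UK Biobank": (0.91, 0.83, 0.99)},
    "ferritin": {"FinnGen": (1.04, 0.85, 1.23), "UK Biobank": (1.17, 1.04, 1.29)},
}

#: published combined (fixed-effects) ORs, 2 decimals
PUBLISHED_COMBINED_OR: dict[str, float] = {
    "tsat": 1.11,
    "iron": 1.15,
    "tibc": 0.92,
    "ferritin": 1.13,
}

#: sepsis cases in the outcome cohort diagnosed before age 75, and in total
SEPSIS_CASES_UNDER_75 = 13_260
SEPSIS_CASES_TOTAL = 16_173


def cohort_estimates(biomarker: str) -> list[CohortEstimate]:
    """The two per-cohort estimates for one biomarker as CohortEstimate records."""
    rows = PER_COHORT_IVW[biomarker]
    return [CohortEstimate.from_or_ci(name, *vals) for name, vals in rows.items()]


def combine_published(biomarker: str) -> MetaResult:
    """Recombine the printed per-cohort rows by fixed-effects meta-analysis."""
    return fixed_effects_meta(cohort_estimates(biomarker))


def under_75_case_fraction() -> float:
    """Fraction of sepsis cases diagnosed before age 75 (a cohort-filter check)."""
    return SEPSIS_CASES_UNDER_75 / SEPSIS_CASES_TOTAL
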