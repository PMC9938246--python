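# Methods

This note documents the statistical models implemented in `ferromr`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## The estimation problem

Two-sample Mendelian randomisation treats germline variants as instruments:
per-variant associations with an exposure (an iron biomarker, in SD units
of the rank-normalised trait) come from one sample, associations with a
binary outcome (sepsis, log-odds) from a disjoint sample. Under the
instrumental-variable assumptions (relevance, exchangeability, exclusion
restriction) the Wald ratio Γ̂ⱼ/γ̂ⱼ estimates the causal log-odds per SD
exposure, and the fixed-effects IVW estimate pools the ratios with inverse
first-order-variance weights wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)². IVW is algebraically the
slope of a zero-intercept weighted least-squares fit of Γ̂ on γ̂ with
weights 1/se(Γ̂ⱼ)²; the test suite checks this identity to 1e-12 relative
against a brute-force loop.

Fixed-effects (not multiplicative/random-effects) variance is used
throughout, i.e. se = (Σwⱼ)^(-1/2) for IVW and the unscaled (X'WX)⁻¹
covariance for MR-Egger. Cochran's Q with J−1 (IVW) or J−2 (Egger) degrees
of freedom reports heterogeneity separately rather than inflating the SE.

### Sensitivity estimators

- **MR-Egger.** Pairs are first oriented so γ̂ⱼ > 0 (joint sign flips leave
  every estimator invariant — a tested property), then Γ̂ is regressed on
  γ̂ with a free intercept. Under InSIDE the intercept estimates the mean
  direct (pleiotropic) effect per exposure-increasing allele and the slope
  remains consistent for the causal effect. p-values use the standard
  normal by default; a t reference with J−2 df is available via
  `t_dist=True` (the convention is not settled, so the default is
  documented rather than asserted).
- **Weighted median.** Ratios sorted, estimate interpolated at cumulative
  normalised weight 0.5; SE from a seeded parametric bootstrap (default
  1,000 resamples of γ̂, Γ̂ from their normal sampling distributions).
  Consistent while variants carrying ≥ 50% of weight are valid.
- **Leave-one-out.** IVW re-estimated excluding each variant in turn,
  labelled by the excluded variant.
- **MR-PRESSO.** Observed statistic Σⱼ (Γ̂ⱼ − β̂₋ⱼ γ̂ⱼ)²/se(Γ̂ⱼ)² with
  leave-one-out IVW predictions; the null is built by simulating
  Γ*ⱼ ~ N(β̂₋ⱼ γ̂ⱼ, se(Γ̂ⱼ)) and γ*ⱼ ~ N(γ̂ⱼ, se(γ̂ⱼ)) (default 1,000
  draws, minimum 500) and recomputing the statistic. Per-variant p-values
  come from each variant's own residual contribution; outliers are declared
  at Bonferroni-adjusted 0.05 and the corrected estimate is IVW on the
  remainder. The distortion test is out of scope. Empirical p-values use
  the (1 + #{≥})/(n_sim + 1) convention, so the global p is floored at
  1/(n_sim+1).

### Instrument construction

Selection keeps variants with p strictly below 5×10⁻⁸, then greedily clumps:
sort by ascending p (ties broken lexicographically on variant id, for
determinism), keep the best, discard everything with r² ≥ 0.01 against it,
repeat. LD is supplied as an external r² matrix — the package never
computes LD from a reference panel, which keeps it download-free; the
generator's `simulate_ld_block` provides correlated-dosage fixtures. The
clump threshold is configurable (0.1 reproduces the looser convention some
analyses use).

Harmonisation aligns outcome records to the exposure's effect allele:
letter-identical pairs are kept, swapped pairs flip the outcome beta,
strand flips are recognised through base complements. Strand-ambiguous
(A/T, C/G) pairs cannot be resolved by letters; by default they are
oriented by allele-frequency agreement unless either frequency is missing
or within 0.08 of 0.5 (both boundaries configurable), in which case they
are dropped. Irreconcilable allele sets are dropped with a diagnostic.
Every input variant leaves harmonisation with exactly one recorded action
(kept / flipped / proxy_substituted / dropped_palindromic / dropped_missing
/ dropped_incompatible) — record conservation is a tested law. Missing
outcome variants can be rescued by the best LD proxy with r² strictly
above 0.8, with alleles mapped through the supplied correspondence.

Instrument strength is summarised per variant as F = (γ̂/se(γ̂))², with a
warning below the conventional threshold of 10.

## The synthetic-data generator

The generator is the package's stand-in for the real cohorts and defines
the conditions under which the calibration claims are made.

- Genotypes gⱼ ~ Binomial(2, fⱼ), fⱼ ~ U(0.05, 0.5), independent variants.
- Exposure X = Σⱼ γⱼ(gⱼ − 2fⱼ) + ε with γⱼ² · 2fⱼ(1−fⱼ) = h²/J (equal
  variance explained per variant; the per-variant effect-size distribution
  of real instruments is unknown, so equal-variance is a documented
  modelling choice), random effect-allele signs, ε ~ N(0, 1−h²). Default
  h² = 0.20 matches the instrument R² used in the power calculation.
- Sepsis ~ Bernoulli(logistic(α + θX + Σⱼ δⱼgⱼ)); α is solved by bisection
  so the realised marginal prevalence matches the target (default 2.5%, the
  frequency of incident cases in the population cohort emulated;
  tolerance 1e-6, with an explicit failure naming `outcome_prevalence` when
  unattainable). Default θ = 0.15 log-odds/SD (OR ≈ 1.16, the magnitude of
  the published biomarker effects).
- Pleiotropy δⱼ: `balanced` N(0, s²) on all variants; `directional`
  N(s, (s/2)²); `outlier` zero except on n chosen variants. Directional and
  outlier effects are injected relative to the exposure-increasing allele
  (multiplied by sign(γⱼ)) — otherwise random effect-allele signs would
  scramble the direction and "directional" pleiotropy would average to
  zero after estimator orientation. Balanced and directional satisfy
  InSIDE; the outlier mode violates it.
- Haemoglobin = 135/151 g/L (female/male) + λX + N(0, 10²), λ default
  1 g/L per SD — small enough that residualised and raw haemoglobin
  correlate > 0.99, mirroring the collider-bias check the stratified
  analysis depends on. Ferritin is log-normal (default log-mean 4.5,
  log-SD 1.0, matching clinical medians of ~50–100 µg/L) with correlation
  0.3 between log-ferritin and the exposure.
- Exposure and outcome cohorts come from disjoint random substreams of one
  seed, sharing the per-variant truth: a genuine two-sample design with no
  sample overlap. A `replicate` index provides further independent outcome
  cohorts for cross-cohort meta-analysis. Identical parameters give
  byte-identical outputs.

Per-variant GWAS uses closed-form simple linear regression for the exposure
and a vectorised two-parameter Newton solver for the logistic outcome scans
(one intercept+slope problem per variant, solved simultaneously; verified
against statsmodels to 1e-6 in the tests). Monomorphic variants are
reported with infinite SE and an explicit flag, never silent NaNs.

**What the generator does not emulate:** genome-wide LD structure (variants
are independent except in the dedicated LD-block fixture), population
structure and ancestry, winner's curse in instrument discovery, age
structure, assortative mating, and selection into testing. Passing
calibration tests on this generator therefore demonstrates correctness of
the estimators under their stated assumptions — not robustness to every
bias that can affect real cohort data.

## Simulation studies (`ferromr.experiments`)

Problem sizes were fixed as part of the study design:

- **IVW calibration:** 200 replicates, 25 instruments, θ = 0.15,
  n = 50,000 per sample, no pleiotropy. Claims: |bias| < 0.01 and 95% CI
  coverage ≥ 92%.
- **Egger recovery:** 100 replicates, directional scale 0.02; the mean
  intercept should sit within 2 Monte-Carlo SEs of the mean realised
  directional effect.
- **Weighted-median robustness:** 10 instruments of which 3 (30%) carry a
  common-direction direct effect of 0.15 log-odds; outcome GWAS of
  n = 200,000 (population case-control scale). With few instruments the
  median's finite-noise bias (≈ Φ⁻¹(m/J_valid)·σ_ratio) stays well inside
  its sampling SE, while IVW is biased by the full weight share of the
  invalid variants — the regime the estimator comparison is meant to show.
  With many instruments the median's SE shrinks faster than its bias, so a
  large-J version of this design would not separate the estimators.
- **MR-PRESSO:** 50 clean and 50 single-outlier replicates; the planted
  direct effect (0.5 log-odds) is sized to exceed the Bonferroni detection
  threshold even for the noisiest (lowest-frequency) instruments.
- **Stratified PRS ordering:** 100 replicates at n = 50,000 with the causal
  effect 0.45 in anaemic vs 0.15 in non-anaemic individuals (a 3× effect
  modification, chosen a priori to give ~90% per-replicate power to order
  the strata correctly given only ~130 sepsis cases in the anaemic
  stratum).

## Stratified PRS analysis

The polygenic score S = Σⱼ wⱼgⱼ uses the exposure effect sizes as weights
and is standardised to mean 0, SD 1 once, cohort-wide; per-stratum ORs are
per SD of this global scale and are never re-standardised within strata
(otherwise they would not be comparable). Stratifying directly on
haemoglobin or ferritin would condition on a collider (the PRS influences
both), so the biomarker is regressed on the PRS by OLS and strata are cut
on *grand mean + residuals*: residuals alone are centred near zero, which
would make absolute clinical thresholds meaningless, while adding back the
grand mean preserves clinical units exactly and leaves the stratifying
variable orthogonal to the PRS (tested to 1e-10). Boundary conventions
follow the printed inequalities: "anaemic" and "iron deficient" are strict
upper bounds (Hb < 125/135 g/L; ferritin < 50 µg/L), 50 and 450 µg/L
belong to "normal", ferritin > 450 µg/L is "high".

The direction of the residualising regression is ambiguous in prose
descriptions of this design ("regression of a PRS on haemoglobin" vs
"removes the PRS effect on each biomarker"); the implementation follows the
second reading (biomarker on PRS), and `direction="prs_on_biomarker"`
provides the alternative for comparison without asserting either as
canonical. Per-stratum logistic models are unadjusted by default (whether
the original stratified models adjusted for age/sex is unstated); strata
with no cases, no controls, or separation are flagged, never silently
dropped. The phenome-scan step is deliberately re-implemented as a plain
per-covariate regression scan (linear for continuous, logistic for binary
covariates), not as a port of any specific MR-PheWAS software.

## Observational model

Cohort rules: ferritin values above 10,000 µg/L are excluded as implausible
before index selection; the index measurement is the first test dated
strictly after recruitment; one record per participant. Exclusion counts
are logged by rule.

The linear model is logistic regression of sepsis on ferritin/100 (so the
OR is per 100 µg/L) with covariates; categorical covariates are one-hot
encoded with the largest category as reference (deterministic). An optional
left-truncation at 50 µg/L drops likely iron deficiency before fitting.

The spline model uses the restricted cubic basis in truncated-power form
with linear tails; k knots give k−1 columns (identity + k−2 nonlinear
terms, normalised by (t_k − t_1)²). Default knots sit at the
{0.05, 0.275, 0.5, 0.725, 0.95} quantiles of the observed predictor — the
conventional 5-knot default of the spline-modelling tradition this follows;
count and locations are configurable. Dose–response curves are reported as
OR(x) = exp(η(x) − η(ref)) with delta-method CIs from the coefficient
covariance; the reference defaults to the cohort median (a documented
choice — the convention is unstated in most reports), OR(ref) ≡ 1 with a
zero-width interval, and a reference outside the knot span triggers an
extrapolation warning.

All general logistic fits go through `fit_logistic` (Newton maximum
likelihood via statsmodels) with explicit failure modes: rank-deficient
designs and separation raise; non-convergence raises with the iteration
trace. The tests pin it against the closed-form 2×2-table log-OR (1e-8) and
an independent scipy likelihood maximisation.

## Meta-analysis and power

Published per-cohort ORs enter on the log scale with
se = (ln CI_high − ln CI_low)/(2·1.959964); the 6-decimal quantile (rather
than 1.96) minimises rounding drift when recombining printed 2-decimal
tables, which still carries a residual error of ~0.005 on the OR scale.
Combination is fixed-effects inverse-variance with normalised weights and
Cochran's Q. Recombining the printed per-cohort rows reproduces the printed
combined ORs for iron, TIBC and ferritin to ~0.01; the published combined
TSAT row is internally inconsistent across report locations (1.09 vs 1.11),
so the TSAT recombination is reported but not asserted anywhere.

Power: Φ(|ln OR|·√(n·R²·p(1−p)) − z_{1−α/2}) with p the case fraction. A
"case-to-control ratio of 40" is read as 40 controls per case (p = 1/41);
this reading reproduces the published 99.4% for OR 1.1 at n = 460,000,
R² = 0.20, α = 0.05.

## Pipeline

`run_pipeline` executes simulate → GWAS → selection → harmonisation → MR
suite per outcome cohort → cross-cohort meta-analysis → stratified PRS →
observational model → power from one YAML config. The config is
schema-validated up front (unknown keys reject), per-stage seeds derive
deterministically from the global seed, every stage logs parameters and
record counts, and identical configs produce byte-identical outputs. The
JSON summary contains every number in the emitted TSV tables. Exit codes in
the CLI distinguish config errors (2), data errors (3) and estimation
failures (4).

## Known limitations

- Estimator validation is against the generator's assumptions; see the
  generator caveats above.
- The weighted median inherits a finite-sample bias toward contaminated
  ratios that grows with per-variant noise; its bootstrap SE reflects this
  regime but the estimator should not be read as unbiased under 30%
  contamination, merely as far less biased than IVW.
- MR-PRESSO's distortion test, multivariable MR, non-linear MR and
  colocalisation are out of scope; the stratified PRS analysis is the only
  non-linearity probe.
- LD handling is limited to externally supplied r² matrices and simple
  equicorrelated fixtures; multi-allelic variants and build liftover are
  unsupported.
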