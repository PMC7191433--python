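# Methods

This note records the statistical model, the calibration of the synthetic
cohort, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The hierarchical exposure model

Repeated clinical fasting-glucose measurements `X_ij` (mg/dL) and
HbA1c-derived glucose equivalents `Y_ij = 28.7 × HbA1c_ij − 46.7` are
modelled as conditionally independent given a participant's latent long-term
average `μ_i`:

    X_ij ~ N(μ_i, σ_X²),  Y_ij ~ N(μ_i, σ_Y²),  μ_i ~ N(θ, τ²).

Integrating `μ_i` out, participant i contributes a multivariate normal with
mean `θ·1` and covariance `τ²·J + diag(σ²_channel)`; the rank-one structure
gives an O(1)-per-participant likelihood from the sufficient statistics
(counts, sums, sums of squares per channel). The four parameters are
estimated by Nelder–Mead maximization on `(θ, log τ², log σ_X², log σ_Y²)`
— the log scale enforces positivity — started from method-of-moments values
(pooled within-person variance for the σ², between-mean variance minus the
expected sampling contribution for τ²), with tolerance 1e-8 on the
log-likelihood and an iteration cap of 500 per parameter. Data in which
every value is identical short-circuit to the boundary solution
(θ = value, τ² = σ_X² = 0).

Per-participant exposure is the plug-in (empirical-Bayes) posterior mean
and variance; parameter uncertainty in `(θ, τ², σ², σ_Y²)` is deliberately
not propagated, matching standard empirical-Bayes practice. With no
measurements in the window a participant receives the prior (θ, τ²).

**σ_Y² identifiability.** HbA1c values are sparse (~3% of participants, one
value each), so σ_Y² is informed only by participants carrying an HbA1c
value alongside other measurements. When fewer than 3 such participants
exist, σ_Y² is fixed at 1.5 × σ_X² (configurable) and flagged on the result
— HbA1c-derived averages plausibly carry extra conversion error, hence a
multiplier above 1.

**Within-person SD.** Glycemic variability is the sample SD of a
participant's pooled observed glucose-equivalent values (both channels),
defined only when ≥2 values exist. An alternative posterior-predictive SD,
`sqrt(posterior_var + σ_X²)`, is available behind the
`posterior_predictive_sd` flag; the observed-value SD is the default
because it is the directly reproducible reading of "SD of the measurements".

**Windowing** keeps days in `[0, 365.25 × window_years]`, closed on both
ends (default 5 years). A single window-wide average is produced; a
time-varying (per-year) exposure is out of scope.

## The synthetic cohort

The generator emulates a community cohort of adults aged ≥45 followed ~5
years with annual-scale glucose measurement. Defaults (see
`simulate.default_config`):

| parameter | default | rationale |
|---|---|---|
| n_participants | 12,321 | cohort size being emulated |
| θ | 106.7 mg/dL | cohort mean fasting glucose |
| τ | 19.5 mg/dL | so that a single measurement's SD `sqrt(τ² + σ_X²)` ≈ 21.9 mg/dL, the cohort's cross-sectional FPG SD, and so that P(μ ≥ 126) ≈ 0.16 makes the diabetes-assignment rule below yield ≈1,011 diagnosed participants |
| σ_X | 10 mg/dL | within-person biological + assay noise; yields within-person SD quartile cutpoints on the scale of the reported 5.9/8.9/13.8 mg/dL |
| σ_Y | 15 mg/dL | 1.5 × σ_X, the same inflation the estimator defaults to |
| mean_glucose_visits | 40,975/12,321 ≈ 3.33 | matches the total glucose-measurement count; counts are 1 + Poisson(mean−1), ensuring ≥1 measurement |
| hba1c_fraction | 367/12,321 ≈ 0.030 | matches the HbA1c count, one value per carrier |
| baseline_hazard | 0.0024 /person-year | reference-category hazard calibrated so the cohort-level 5-year cumulative incidence lands near 2.26% once category and covariate effects are applied (~276 events at full scale) |
| category_log_hr | ln(0.74, 1, 1.11, 1.29, 1.78, 1.89) | the fully adjusted total-stroke category hazard ratios used as generating truth |
| covariate_effects | age 0.05/yr, male 0.35, SBP 0.012/mmHg, current smoking 0.4 | conventional stroke risk-factor magnitudes |
| fatal_fraction | 146/279 | fatal share among events |
| censoring_rate | 0.02 /person-year | mild random loss; administrative censoring at 5 years dominates |

Covariates are drawn from independent parametric laws matched to the
cohort's marginals (age N(60.8, 10.2²) truncated at 45, 53.7% female, BMI
N(23.6, 3.1²), SBP N(141, 20.4²), total cholesterol N(185.1, 34.3²),
smoking 67/25/8% never/current/former, etc.). Measurement times are uniform
over follow-up (the annual-visit calendar is not modelled). Diabetes is
"diagnosed" with probability 0.5 when μ_i ≥ 126 mg/dL, else the participant
stays nondiabetic — mimicking undiagnosed diabetes remaining in the
nondiabetic stratum. Event times are exponential with rate
`baseline_hazard × exp(category log HR + covariate effects)` using the
*latent* category (values below 80 mg/dL fall into the lowest bin on the
generating side), censored at min(exponential censoring, 5 years); event
type is fatal with probability `fatal_fraction`, independently.

Randomness uses one root seed spawning per-participant substreams
(`numpy.random.SeedSequence`), so cohorts are reproducible and
order-independent.

**What the generator does not emulate:** correlation between covariates
(only marginals are matched), visit-level missingness mechanisms, competing
non-stroke mortality, assay drift, seasonal effects, and any non-normality
or mixture structure in the latent glucose distribution (a diabetic
sub-population would make it right-skewed; the single normal is the model's
own assumption). Passing tests therefore demonstrate internal correctness
and calibration under the assumed model, not robustness to real-data
violations of it.

## Analysis-table construction

- Category bins are half-open `[lo, hi)`: 126.0 falls in 126–139.9 and
  140.0 in ≥140 — one-decimal range labels imply this reading. Reference is
  90–99.9 (ordinal 2).
- Estimated averages below 80 mg/dL fall outside the categorization range
  and are excluded with a logged count.
- SD quartile cutpoints use the median-unbiased quantile convention; values
  tied with a cutpoint go to the lower quartile; degenerate (tied) cutpoints
  warn. Cutpoints are data-dependent and logged, never constants.
- Hypertension = SBP ≥ 140 or DBP ≥ 90 or reported history;
  hypercholesterolemia = total cholesterol ≥ 240 mg/dL (both boundaries
  inclusive).
- Assembly inner-joins baselines, exposure estimates and outcomes on
  participant id, records every exclusion, and rejects duplicate ids.

## Survival models

- Cox partial likelihood with the Efron tie correction (lifelines), on the
  follow-up time scale; baseline age is an adjustment covariate. The
  Newton–Raphson tolerance is tightened to 1e-14 because the library default
  halts one small step short of the maximizer (visible against a brute-force
  oracle at 1e-6).
- Cause-specific hazards: for nonfatal (fatal) stroke the other type is
  censored at its event time. Fine–Gray competing-risk models are out of
  scope.
- Adjustment sets are exactly nested (none ⊂ age+sex ⊂ full model 3);
  categorical covariates are treatment-coded with never/none/female
  reference. Adjustment columns that are constant within a stratum (sex
  within sex subgroups) are dropped.
- P-for-trend enters the 1-based ordinal level as a single linear term;
  per-level median scores are available via `trend_scores="median"`.
- Wald 95% CIs use z = 1.959964; all p-values two-tailed.
- Exposure levels with zero events cannot support a finite HR: their rows
  are left out of the categorical fit and the level is reported with absent
  estimates. Apparent complete separation (|coef| > 15) raises a fit error
  naming the level.
- Spline curves: natural cubic basis (patsy `cr`) whose complete knot set is
  the 5th/35th/65th/95th percentiles of the analysis sample's estimated
  average; the redundant constant direction is removed before fitting (the
  partial likelihood is invariant to it). Curves are centered at 95 mg/dL
  (midpoint of the reference category) with delta-method bands; the band
  width is zero at the reference by construction.
- `run_all_models` executes the full grid — 3 outcomes × 3 models × {all,
  nondiabetic} for categories, model-3 SD-quartile fits for both strata
  (quartiles recomputed within the nondiabetic stratum), total-stroke spline
  curves, and model-3 subgroup fits by sex and hypertension — recording
  failures per cell and continuing.

## Known limitations and expected behaviour

- Categorizing on estimated (shrunken) averages misclassifies participants
  near bin edges, so end-to-end category HRs are attenuated toward 1
  relative to the generating values; the hazard-ratio recovery check in the
  acceptance suite therefore fits on the latent categories, isolating the
  survival model, while the shrinkage checks quantify the exposure-side
  error directly (MSE ratio ≈ 0.85–0.9 under default conditions).
- With ~3 measurements per participant, posterior SDs are ≈5 mg/dL; bins
  narrower than ~10 mg/dL cannot be sharply resolved per participant.
- The trend test's type-I error is checked by permutation at ~100 events;
  Wald tests in Cox models are mildly conservative at that event count.
- Problem sizes in the test suite (cohorts of 1,200–12,321; 20 simulation
  replicates; 400 permutations) are chosen to give stable Monte-Carlo
  checks at interactive runtimes.
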