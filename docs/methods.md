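# Methods

## The problem

Prognostic Cox models for observational cohorts are conventionally
trained on every available patient. When treatment assignment is
confounded with prognosis — healthier patients preferentially receiving
therapy — the cohort is dense in some risk regions and sparse in others,
and a single model fit to it concentrates its attention on the dense
mid-risk bulk. `stratmatch` implements a two-stage alternative: select a
*prognostically balanced* training set by optimal matching of treated and
untreated patients within strata of predicted baseline risk, then train
separate arm-specific Cox models on the matched sets.

## Stage 1: risk stratification and matching

**Baseline risk.** A Cox proportional-hazards model is fit on the
untreated arm only, without the treatment column, and applied to the
whole cohort to predict each patient's probability of death within the
horizon (default 60 months): `risk = 1 − S0(h)^exp(β'x)` with the
Breslow baseline `S0`. Because the model never sees treatment, predicted
risks are counterfactual no-treatment risks for everyone.

**Strata.** Risks are binned into S = 10 *fixed-width* probability bins
of width 1/S, half-open `[lo, hi)` with the last bin closed — stratum 3
is risk 0.2–0.3. Fixed-width bins (rather than empirical quantiles) are
what makes the bins comparable across arms and what produces the large
stratum-size imbalances the method is designed to correct.

**The quota α.** α is the smallest stratum-by-arm patient count that
still reaches a cutoff (default 20). Strata whose smaller arm holds at
most α patients are matched exactly 1–1 (nothing is discarded from the
minority); larger strata contribute exactly α matched pairs each, so
every risk region is equally represented in the matched training set.

**Distances.** Within a stratum, covariates (one-hot encoded, reference
level dropped) are standardized using the mean and sample SD of the
pooled stratum members — pooling the arms keeps cross-arm distances on a
common scale; zero-variance columns map to 0. The distance between an
untreated and a treated patient is the Euclidean norm of the difference
of standardized vectors.

**The three formulations.** With binary pair-selection variables and
nonnegative distances, all three are solved to *global* optimality:

* *equalized* — each patient used at most once, exactly α pairs,
  minimum total distance. Solved by rectangular assignment
  (`linear_sum_assignment`) after appending `m − α` dummy columns whose
  cost is strictly below any real cost, which forces exactly α real
  pairs.
* *exact 1–1* — every minority patient matched to exactly one distinct
  majority patient (small strata). Solved by rectangular assignment
  directly.
* *relaxed* — each patient usable up to twice (matching with
  replacement), exactly α pairs. Solved as a linear program over the
  bipartite-flow polytope (HiGHS dual simplex); basic optima of this
  polytope are integral, the solution is checked for integrality, and an
  exact MILP fallback covers any fractional vertex.

Cardinality is imposed as an equality (Σz = α): since distances are
nonnegative, the ≥ α optimum always selects exactly α pairs, so the two
are equivalent and the equality keeps tie-break perturbations from
over-selecting zero-distance pairs. Ties among equally optimal matchings
are broken lexicographically on (row, column) via a geometric reward
perturbation (ε·2^−rank) applied on small instances (|A|·|B| ≤ 64),
where exact lexicographic order is meaningful and testable; large
instances rely on the deterministic solver. A brute-force enumerator
(vectorized over all pair subsets, |A|·|B| ≤ 36) provides the
independent optimum in tests.

**Oversampling.** The matched training multiset can be duplicated or
tripled; the distinct-patient census is unchanged, only row
multiplicities grow. Replication creates tied event times, so under
Efron's tie correction the refit coefficients are near- but not
bit-identical to the unreplicated fit (observed drift ~1e−3); standard
errors shrink by ≈ 1/√factor.

## Stage 2: the model suite

* `model1` — whole cohort, treatment as a binary covariate (the
  standard-practice comparator);
* `model2A` / `model2B` — untreated / treated arms;
* `model3A` / `model3B` — matched untreated / treated arms (the
  proposed method), with optional oversampling;
* `psmA` / `psmB` — arms after 1:1 nearest-neighbor propensity-score
  matching without replacement (greedy on the logit of the propensity,
  minority arm in descending score order; caliper 0.2 × SD(logit) for
  the GLM propensity, no caliper for the random forest).

All fits are partial-likelihood Cox models (Efron ties, Breslow
baseline) via lifelines, run at Newton precision 1e−10 so that in-sample
calibration slopes equal 1 to ~1e−11 (the identity is exact at the MLE;
looser optimizer tolerances leave visible slack).

## Metrics

* **Harrell's C** — pairs usable iff the shorter time is an event; tied
  times with both events unusable; tied risks count ½. (lifelines'
  implementation matches these conventions exactly; an independent
  pairwise enumerator backs it in the tests.)
* **Uno's C** — IPCW concordance truncated at the horizon, weights
  1/Ĝ(t)² from the censoring Kaplan–Meier (scikit-survival). If Ĝ hits 0
  before the horizon the truncation time is pulled back with a warning.
* **Brier score** — Graf's IPCW estimator at the horizon: events before
  the horizon weighted 1/Ĝ(t−), survivors 1/Ĝ(h), censored-before-horizon
  weight 0 (cross-checked against scikit-survival).
* **OE ratio** — (1 − KM(h)) / mean predicted risk.
* **ICI / E50 / E90 / Emax** — mean / median / 90th-percentile
  (linear-interpolation order statistics) / max of |smoothed observed −
  predicted|. The smoothed observed probability comes from a Cox
  recalibration of the outcome on a restricted cubic spline (3 knots at
  the 10th/50th/90th percentiles) of cloglog(predicted risk); a constant
  risk vector degenerates to the Kaplan–Meier estimate for everyone.
* **Calibration slope** — coefficient of the model's linear predictor
  refit on evaluation data; exactly 1 in-sample.

## Bootstrap validation

Efron/Harrell optimism correction with B = 100 resamples: refit the
recipe on each with-replacement resample, score it on the resample
(train) and on the original rows (test); optimism = mean(train − test);
corrected = apparent − optimism (an exact identity in the report).
Percentile 95% intervals come from the B test values. Resampling covers
the model fit only — matched/oversampled cohorts are resampled as the
row multisets they are; matching is not re-run inside the loop (a
caller-supplied recipe can re-run it for sensitivity analysis). The
apparent and train-side calibration slopes are identically 1 by MLE
self-consistency, so the corrected slope reduces to the mean bootstrap
slope on the original data. Resamples with no events (or degenerate
columns) are redrawn, at most 10 times.

## Synthetic cohorts

The generator emulates the observational structure the method targets:
n = 1,800 patients; 4 standard-normal continuous, 4 Bernoulli binary
(prevalence 0.4 by default) and 2 three-level categorical covariates;
treatment from a logistic propensity whose coefficients are negatively
aligned with the outcome coefficients (healthier patients treated, ~2/3
treated); Weibull-baseline proportional hazards (shape 1 by default, so
closed-form exponential checks apply; baseline 5-year survival 0.5);
independent uniform-window censoring whose window is bisected to hit a
target rate (default 0.35, near the follow-up pattern of a mature
oncology cohort). Ground truth (coefficients, linear predictors, horizon
risks, uncensored times) is returned for recovery tests.

Three optional knobs generate the *heterogeneous* regimes the method is
motivated by, and default to off:

* `binary_prevalence` — rare strong binary covariates produce a
  mid-peaked risk distribution with thin, predictable tail strata;
* `treatment_effect_sd` — per-patient random treatment response
  (unobservable to any model), making treated outcomes intrinsically
  noisier than untreated ones;
* `interaction_strength` — pairwise covariate products in the true log
  hazard only, so the covariate–outcome relation varies across the risk
  range and every linear fit is a training-distribution-weighted
  projection.

What the generator does *not* emulate: informative censoring, real
marginal covariate distributions, measurement error, non-proportional
hazards over time. Passing tests show the pipeline's internal
correctness and the method's directional behavior under its assumed
structure, not clinical performance.

A note on the method-level comparison: under a correctly specified
linear proportional-hazards truth, the full-cohort model is the
asymptotically efficient fit and matched-cohort models cannot beat it —
training-set composition only matters under misspecification or
heterogeneity. The motivating-regime test therefore uses the rare-tail /
heterogeneous-response configuration above, which also reproduces the
qualitative ordering seen on real confounded cohorts (arm-specific
models edge out the pooled model before matching adds its gain).

## Problem sizes and numerical choices

Simulation-based tests run at n = 1,000–6,000 with 20 seeds for
directional claims and 30 replicates for coverage claims; solver–oracle
equivalence uses 200 random instances with arms up to 6. Bootstrap
refits inside validation warm-start from the apparent fit at standard
Newton precision (1e−7) — rank-based metrics are insensitive to the last
optimizer digits — with a cold high-precision retry on failure.
Propensity scores are clipped to [1e−6, 1 − 1e−6]. Degenerate inputs are
errors, not silent results: no events, constant design columns, constant
linear predictors, empty metric inputs.

## Known limitations

Single global α (no per-stratum quotas); simple median/mode imputation
rather than chained multiple imputation; no regularized or stratified
Cox, time-varying covariates, or competing risks; PSM comparator is
greedy nearest-neighbor only (no optimal or k:1 PSM); calibration
smoothing assumes enough risk spread for spline knots (falls back to a
linear term when knots collide).
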