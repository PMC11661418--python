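# stratmatch

**Prognostic stratum matching for survival models on confounded
observational cohorts.**

## The problem

Prognostic Cox models are almost always trained on the entire available
cohort. On observational data this is a trap: patients with favorable
profiles are more likely to receive treatment, so the cohort is dense in
some prognostic regions and sparse in others, and the fitted model
quietly concentrates on the dense mid-risk bulk. `stratmatch` implements
a two-stage alternative for biostatisticians and clinical modelers:

1. **Stratify and match.** Fit a baseline Cox model on the untreated
   arm, predict every patient's 5-year mortality risk
   `1 − S0(h)^exp(β'x)`, bin risks into ten fixed-width strata, and —
   within each stratum — optimally match treated to untreated patients
   by minimizing the total Euclidean distance between standardized
   covariate vectors, subject to one of three exact integer
   formulations: *equalized* 1–1 (exactly α pairs per stratum, so all
   risk regions are equally represented), *exact* 1–1 (small strata:
   keep the whole minority), or *relaxed* (each patient usable twice).
2. **Train on the matched arms.** Fit separate Cox models on the
   matched untreated and treated sets (optionally oversampled ×2/×3),
   and compare them against the standard full-cohort model and a
   propensity-score-matched benchmark with a complete discrimination and
   calibration suite — Harrell's and Uno's C, Graf's IPCW Brier score,
   OE ratio, smoothed-calibration errors (ICI/E50/E90/Emax), calibration
   slope — validated by Efron/Harrell optimism-corrected bootstrap
   (B = 100).

A seeded generator of confounded synthetic cohorts (logistic propensity
on the covariates, Weibull proportional hazards, calibrated independent
censoring, known ground truth) makes the whole pipeline testable
offline. See `docs/methods.md` for the model details and design
decisions.

## Worked example

```python
import stratmatch as sm

cohort, truth = sm.generate_cohort(sm.GeneratorConfig(n=1500, seed=3))
assn = sm.stratify_cohort(cohort)            # stage 1: risks, strata, alpha
print("alpha =", assn.alpha)
matched = sm.match_stratified_cohort(cohort, assn, variant="equalized")
print("matched pairs:", matched.n_pairs)

u, t = sm.split_by_treatment(cohort)
before = sm.standardized_mean_differences(sm.encode(u), sm.encode(t)).abs().mean()
after = sm.standardized_mean_differences(
    sm.encode(matched.untreated), sm.encode(matched.treated)).abs().mean()
print(f"mean |SMD| before {before:.3f} -> after {after:.3f}")

suite = sm.build_model_suite(cohort)         # stage 2: the seven models
print(suite.training_sizes)
print({k: round(v, 4) for k, v in
       sm.evaluate_model(suite["model1"], cohort, 60.0).items()})
```

prints

```
alpha = 23
matched pairs: 187
mean |SMD| before 0.141 -> after 0.025
{'model1': 1500, 'model2A': 561, 'model2B': 939, 'model3A': 187,
 'model3B': 187, 'psmA': 515, 'psmB': 515}
{'harrell_c': 0.7182, 'uno_c': 0.7228, 'brier': 0.1841, 'oe': 0.9934,
 'ici': 0.0019, 'e50': 0.0019, 'e90': 0.003, 'emax': 0.0039,
 'calibration_slope': 1.0}
```

The matching selects exactly α = 23 pairs from every sufficiently
populated stratum (187 pairs total), cuts the mean absolute standardized
mean difference between arms from 0.14 to 0.03, and the in-sample
calibration slope of 1.0 reflects maximum-likelihood self-consistency.

The same pipeline runs from the shell:

```sh
stratmatch simulate --n 1800 --seed 0 --out cohort.csv
stratmatch run-all --config run.yaml -B 100 --seed 0 --outdir results/
```

where `run.yaml` points either at a CSV (with a covariate schema and
column map) or at a synthetic-generator config; outputs are TSV/JSON
tables of training sizes, in-sample metrics, bias-corrected metrics with
percentile CIs, and the stratum census before/after matching.

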