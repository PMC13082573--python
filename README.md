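# ehrcausal

Doubly robust comparative-effectiveness analysis of coded EHR event
streams, with a synthetic-EHR testbed.

The package implements the full pipeline for comparing two second-line
drug classes on a fixed-horizon (5-year) composite outcome:

1. **synthetic EHR generation** (`ehrcausal.synthetic`) — longitudinal
   coded event streams (encounters, medication pairs, demographics, labs,
   windowed confounder codes, outcome/death events) drawn from an additive
   hazards model with confounded treatment assignment, plus a Monte-Carlo
   oracle for the true marginal estimands;
2. **new-user cohort construction** (`ehrcausal.cohort`) — medication
   episodes via the paired-code rule (two same-ingredient codes 30–180
   days apart), index date and arm from the earliest second-line episode,
   strict eligibility (age > 18, prior metformin, established care > 365
   days before index, maintained care > 30 days after), composite outcome
   (first HF hospitalization or death) censored at the last encounter, and
   per-protocol switch flags;
3. **covariate assembly** (`ehrcausal.covariates`) — expert variables with
   nearest-within-a-year retrieval and pooled mean imputation, plus
   per-code counts in two pre-index windows (recent: within 1 year;
   history: more than 1 year) filtered at 5% prevalence;
4. **nuisance models** (`ehrcausal.nuisance`) — adaptive-LASSO logistic
   propensity and outcome models, a penalized Lin–Ying additive hazards
   model with Breslow baseline, and a censoring Kaplan–Meier evaluated
   with left limits;
5. **doubly robust estimation** (`ehrcausal.estimation`) — AIPW risk
   difference and augmented-IPCW survival ratio at the horizon, with
   patient-level bootstrap SDs, normal-approximation CIs (log scale for
   ratios), and intent-to-treat / per-protocol styles;
6. **reporting** (`ehrcausal.balance`, `ehrcausal.report`,
   `ehrcausal.cli`) — standardized-mean-difference balance tables,
   attrition-accounted manifests, results JSON and a markdown report.

## Command line

```sh
ehrcausal simulate --config sim.yaml --out data/          # synthetic event stream
ehrcausal cohort   --events data/events.csv --classes data/classes.yaml \
                   --comparison insulin,sulfonylureas --out run/
ehrcausal estimate --events data/events.csv --classes data/classes.yaml \
                   --covariates covars.yaml --analysis analysis.yaml --out run/
ehrcausal report   --run run/
```

`estimate` writes `cohort.csv` (with exclusion reasons), `covariates.csv`,
`balance.csv`, `results.json`, `manifest.json` and `report.md`.

A minimal `sim.yaml` is produced by `SimConfig().to_yaml(...)`; `analysis.yaml`
accepts `AnalysisConfig` fields plus a `lasso:` block of `AdaptiveLassoSpec`
fields and a `styles:` list.

## Python API sketch

```python
from ehrcausal import (SimConfig, generate_population, build_cohort,
                       build_covariate_matrix, CovariateSpec,
                       estimate_effects, AnalysisConfig)
from ehrcausal.events import default_class_map
from ehrcausal.synthetic import feature_dictionary

cfg = SimConfig(n_patients=2000, seed=7)
events, truth = generate_population(cfg)
cohort, excluded = build_cohort(events, default_class_map(), cfg.comparison)
matrix = build_covariate_matrix(
    events, cohort,
    CovariateSpec(feature_dictionary=feature_dictionary(cfg)),
    classes=default_class_map(),
)
effects = estimate_effects(
    matrix.X, cohort.arm.to_numpy(), cohort.follow_days.to_numpy(),
    cohort.event.to_numpy(), cohort.switched.to_numpy(),
    AnalysisConfig(n_bootstrap=200, seed=1),
)
print(effects["risk_difference"].point, effects["survival_ratio"].point)
```
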