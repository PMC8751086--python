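# icupam

Competing-risks analysis of daily protein intake and hospital outcome in
critically ill patients, built on **piece-wise exponential additive mixed
models (PAMMs)**.

Observational ICU nutrition data are hard to analyse honestly: intake is
time-varying, death and live discharge compete, and sicker patients are
both harder to feed and more likely to die (confounding by indication).
`icupam` implements an analysis pipeline designed for exactly these
problems, for biostatisticians and intensive-care researchers working with
patient-day feeding records:

* **Intake quantification** — daily protein in g/kg from enteral protein
  plus parenteral amino acids × 0.83, classified into level I (< 0.8),
  level II (0.8–1.2) and level III (> 1.2 g/kg per day), with level-II
  imputation after live ICU discharge (and a no-imputation ICU-outcome
  sensitivity mode).
* **PED transform** — follow-up beyond day 4 split into intervals (a, b]
  with log person-time offsets and per-cause event indicators, so each
  cause-specific hazard model is a penalized Poisson regression:
  `log λ_k(t,x) = f_0k(t) + Σ f_jk(x_j) + γ'x + b_ICU + cumulative protein terms`.
* **Lag-lead windows** — a day on diet affects hazards only after a 4-day
  lag and for a lead of twice the cumulative days of medical nutrition
  therapy (dynamic), or 60 days (static sensitivity mode).
* **Penalized fitting** — P-spline smooths, ridge-penalized ICU random
  intercepts (λ = 1/σ²), REML or fixed smoothing, Bayesian covariance.
* **Hypothetical diets** — five 11-day level trajectories contrasted in
  six pairwise comparisons; time-varying cause-specific hazard ratios with
  delta-method 95% CIs and cumulative incidence functions (absolute risks).
* **Synthetic cohorts** — a generator with known ground-truth hazard
  surfaces emulating the (non-public) international nutrition-survey
  schema, so everything is testable end to end.

## Worked example

```python
import numpy as np
import icupam as ip

cfg = ip.SimulationConfig(n_patients=2000, rng_seed=42)
patients = ip.simulate_cohort(cfg)
ped = ip.cohort_to_ped(patients, cause_set="hospital", window_mode="dynamic")

spec = ip.ModelSpec(cause="death", baseline_type="ps", baseline_k=8,
                    linear=["age", "apache2"], random_intercept="icu_id",
                    cumulative=ip.CumulativeSpec(mode="phase", basis="constant"),
                    smoothing={"baseline": 1.0, "re(icu_id)": 16.0})
model = ip.fit(ped, spec)

diets = ip.make_diets()
hr = ip.hr_curve(model, diets["late_standard"], diets["exclusively_low"])
```

Running `examples/03_fit_and_hazard_ratios.py` (which does the above for
both causes) prints:

```
PED: 35641 pseudo-observations, 500 deaths, 1389 discharges

late standard vs exclusively low, death:
  HR on (4,5]            = 1.000  (lag forces exactly 1)
  estimated extreme HR   = 0.943 [0.564, 1.575] on (15,16]
  true HR there          = 0.750

late standard vs exclusively low, discharge:
  HR on (4,5]            = 1.000  (lag forces exactly 1)
  estimated extreme HR   = 1.938 [1.448, 2.594] on (15,16]
  true HR there          = 1.980
```

Reading this: the hazard ratio on the first interval (4, 5] is exactly 1
because the 4-day lag excludes every diet day from its window — a
structural property, not an estimate. At day 15–18 the dynamic window of a
hypothetical diet covers all seven late days (#5–#11), so the true contrast
reaches its extremes (0.75 for death, 1.98 for discharge); the fitted
curves recover them within their confidence intervals. The other examples
cover cohort simulation (`01`), intake classification, imputation and
windows (`02`), and absolute risks for all five diets (`04`).

The full pipeline — inclusion filter, both cause-specific fits, all six
diet comparisons for both causes, CIFs, and artifacts on disk — runs from
one config:

```python
bundle = ip.run(ip.AnalysisConfig(n_patients=1000, seed=7, output_dir="out"))
```

or from the shell via the thin CLI: `icupam simulate | run | fit | compare
| report` (see `icupam --help`). Sensitivity and subgroup variants are
config switches: `outcome_set="icu"` (no post-ICU imputation),
`window_mode="static"`, `subgroup="bmi_gt_30"` or calorie strata.

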