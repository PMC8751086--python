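# Methods

## The model

`icupam` analyses the association between daily protein intake during the
acute phase of critical illness (days on diet #1–#11 after ICU admission)
and the competing outcomes *in-hospital death* and *live hospital
discharge*, using piece-wise exponential additive mixed models (PAMMs).

Follow-up beyond day 4 (inclusion conditions on 96 h of ICU survival) is
partitioned into intervals (a, b] — daily from day 4 to the 60-day
censoring horizon by default — on which each cause-specific hazard is
constant. Each patient contributes one pseudo-observation per interval at
risk with a log person-time offset and a cause-specific event indicator;
on this piece-wise exponential data (PED) the survival likelihood is
proportional to a Poisson likelihood, so the hazard model

    log λ_k(t, x) = f_{0k}(t) + Σ_j f_{jk}(x_j) + γ_k' x_lin + b_ICU
                    + Σ_{t_z} W(t, t_z) g_k(t, t_z) z(t_z)

is fitted as a penalized Poisson regression, separately per cause k, with
the competing event treated as censoring at its time (the standard
cause-specific construction).

## Intake quantification

Daily protein intake in g/kg is enteral protein plus parenteral amino
acids times 0.83 (protein-equivalent conversion); oral intake is ignored
and exclusively-oral days rank in the lowest level. Days are classified as
level I (< 0.8), level II (0.8–1.2, closed interval — the only reading
consistent with the three printed ranges) or level III (> 1.2 g/kg).
Intake enters the model as the two level dummies (II vs I, III vs I), not
as a continuous dose. Input tables already carry g/kg amounts, so no body-
weight convention is imposed by the package; whether g/kg refers to actual
or ideal body weight is a property of the data source.

For hospital outcomes, patients discharged alive from the ICU before day
#11 have the remaining days imputed as standard (level II) intake; imputed
days count as days with medical nutrition therapy (MNT) and carry the
cohort level-II median 0.99 g/kg as a cosmetic numeric placeholder (the
model consumes the category). The ICU-outcome sensitivity analysis
truncates trajectories at ICU discharge and never imputes.

## Lag-lead windows

A day on diet t_z can affect the hazard of interval (t, t+1] only inside a
window: after a 4-day lag (guarding against indication bias — intake often
changes just before death or discharge) and for a lead time of twice the
cumulative number of MNT days, m(t_z) ("dynamic" mode):

    W(t, t_z) = 1  iff  t_z + 4 ≤ t_start < t_z + 4 + 2·m(t_z).

The "static" sensitivity mode replaces the lead by 60 days. Comparisons use
the interval's left endpoint, so the first interval (4, 5] is structurally
untouched by any diet day: every hazard-ratio curve equals exactly 1 there,
with a degenerate confidence interval. m(t_z) counts MNT days up to and
including t_z; for hypothetical diets the full-MNT convention m(t_z) = t_z
applies. Days on diet are aligned with follow-up time as t_z = j (the
sub-day offset between calendar feeding days and the 24-h admission clock
is unidentifiable at daily intake resolution and is ignored).

## Cumulative-effect parameterizations

Two bases for the cumulative terms are provided:

* **phase** (default): the window-weighted counts of level-II and level-III
  days, split into early (#1–#4) and late (#5–#11) acute phase, each
  multiplied by a coefficient function of follow-up time (P-spline of size
  5, or a constant). Four counts × two levels capture the early/late
  distinction the hypothetical diets are built on.
* **surface**: a full tensor-product P-spline surface g(t, t_z) per level
  dummy (5×5 marginal bases), contracted against the window indicators.

The phase counts are exactly the phase-wise sums of the surface
representation, which is checked property-wise.

## Estimation

Penalized IRLS maximizes Σ[δη − exp(η + offset)] − ½ Σ λ_m β'S_m β with
step-halving; smooth terms are cubic B-splines on equally spaced knots with
second-order difference penalties, centered (sum-to-zero) where they would
be confounded with the intercept. The ICU random intercept is an identity-
penalized block using the mixed-model-as-penalty identity λ = 1/σ².
Smoothing parameters are selected by a Laplace-approximate REML criterion
(Nelder–Mead on log λ with a nested PIRLS), or fixed by the user — fixed
values are the default in the pipeline so that repeated runs are bit-for-
bit identical. The reported covariance is the Bayesian posterior covariance
(X'WX + S_λ)^{-1}; design columns that are identically zero (e.g. basis
functions of an early-phase coefficient supported after every early window
has closed) are dropped with a warning and restored as zero coefficients.

Numerical safeguards: η + offset capped at 30 before exponentiation, a
1e-8 ridge on the penalized Hessian, iteration cap 200 with a convergence
tolerance of 1e-10 on the penalized log-likelihood. Unpenalized, covariate-
free fits on a coarse grid reproduce the closed-form occurrence/exposure
rates (events / person-days) to < 1e-6 relative error, and agree with an
independent GLM implementation.

## Diets, hazard ratios, absolute risks

Five hypothetical diets (11-day level trajectories) and six pairwise
comparisons are predefined. Days a diet leaves unspecified are copied from
the comparison diet; applied literally this rule would make late-standard
vs early-standard identical, so the package pins late-standard (and the
Fig-2 family generally) at level I on days #1–#4 and resolves the
standard-vs-high family in the level-II context: late-high = II on #1–#4 +
III on #5–#11, early-high = III on #1–#4 with late days copied from its
partner (II against standard, III against late-high). Every pair is then
component-wise ordered and the reference always provides fewer protein.

Hazard ratios are computed under the ceteris paribus assumption: the
linear-predictor difference between two diets reduces to the cumulative-
term contrast (confounders and the ICU intercept cancel), HR(t) =
exp(Δη̂(t)) with delta-method 95% CIs (z = 1.96). Cumulative incidence
functions combine both cause-specific models for a population-average
profile (random intercept 0, categorical confounders at reference,
continuous confounders at training medians) using the piece-wise constant
closed form with proportional within-interval cause allocation; the
identity CIF_death + CIF_discharge + S = 1 holds to machine precision and
is asserted for every fitted model and diet.

## The synthetic cohort generator

The survey database behind the original analysis is not deposited, so the
generator emulates its schema and statistical structure with known ground
truth:

* **Intake**: first-order Markov chain on {I, II, III} with stationary
  distribution (0.440, 0.328, 0.232) and persistence 0.5 (P = 0.5 I +
  0.5·1π'), g/kg values uniform on the published IQRs (medians ≈ 0.49 /
  0.99 / 1.41), 15.3% of days with a PN component, 3% exclusively-oral
  days.
* **Outcomes**: constant baseline hazards 0.0138/day (death) and
  0.0375/day (discharge) on days 4–60, reproducing the ~25% / ~69% / ~6%
  outcome mix; event times are continuous within days (inverse-CDF within
  the event interval).
* **True cumulative effects** act through the same lag-lead windows the
  analysis estimates, with per-day late effects log(0.75)/7 (death, levels
  II and III) and log(1.98)/7 / log(1.98·0.19)/7 (discharge, II / III), so
  a window covering all seven late days reproduces the benchmark
  full-window HRs 0.75, 1.98 and 0.376; early effects are null.
* **Confounders** are drawn independently of intake (age and APACHE II
  carry modest true effects; the rest are pure noise covariates); ICU
  random intercepts are N(0, 0.25²) shared within ICU. An optional
  `indication_bias` scenario couples a latent severity to both intake and
  the death hazard.
* **ICU discharge** before day #11 is an independent daily Bernoulli
  process (p = 0.04, days 5–10; ~20% of patients), exactly the group whose
  trajectories are imputed. Discharge after day #11 is not modelled: such
  patients carry their hospital outcome as their ICU outcome in the
  sensitivity mapping. The hospital outcome continues under the same
  hazard model after ICU discharge, and the true hazard uses the imputed
  (hospital-mode) trajectory — so the primary analysis is correctly
  specified by construction and the ICU sensitivity analysis probes the
  imputation assumption.

What the generator does **not** emulate: realistic case-mix and diagnosis-
specific hazards, time-varying baseline shapes, informative ICU discharge,
within-day feeding patterns, or calorie intake beyond a level-correlated
fraction-of-target scalar. Passing recovery tests therefore demonstrate
that the estimation machinery recovers effects of the assumed form under
the assumed censoring/imputation structure — not that the original
cohort's estimates are reproducible.

## Problem sizes and checks

The unit suite runs on cohorts of 50–2000 patients. Parameter recovery is
checked two ways: a single n = 2000 cohort whose estimated late-standard-
vs-low HR curve must cover the true curve, and 100 replicates at n = 500
whose pointwise 95% CI coverage of the truth must lie in [90%, 99%]
(observed ≈ 94%). At n = 500 the minimum-HR estimator has a sampling sd of
roughly 0.27 around a truth of 0.75 — the information in ~125 deaths
passing through a 4-day-lagged window bounds how sharply a cumulative
effect can be localized, which is why the recovery check is posed as CI
coverage rather than a tight point tolerance.

## Known limitations

* REML selection uses derivative-free outer optimization; it is adequate
  for the handful of smoothing parameters used here but slower than a
  full Newton scheme, and no uncertainty is propagated from λ.
* Subdistribution (Fine–Gray) hazards are out of scope; absolute risks
  come only from combining the two cause-specific fits.
* Left truncation is handled solely by conditioning on survival to day 4.
* The exclusion tally reproduces the flow-chart order but real-database
  counts are not reproducible from synthetic data and are reported, not
  asserted.
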