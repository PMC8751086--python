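"""Fit both cause-specific models and contrast hypothetical diets.

Simulates a cohort with a known true effect (late standard vs low full-
window death HR 0.75, discharge HR 1.98), transforms it to piece-wise
exponential data, fits the two penalized Poisson hazard models and prints
the estimated time-varying hazard-ratio curves against the ground truth.
"""

import numpy as np

import icupam as ip

cfg = ip.SimulationConfig(n_patients=2000, rng_seed=42)
patients = ip.simulate_cohort(cfg)
ped = ip.cohort_to_ped(patients, cause_set="hospital", window_mode="dynamic")
print(f"PED: {len(ped)} pseudo-observations, "
      f"{int(ped['d_death'].sum())} deaths, {int(ped['d_discharge'].sum())} discharges")

spec = lambda cause: ip.ModelSpec(
    cause=cause, baseline_type="ps", baseline_k=8,
    linear=["age", "apache2"], random_intercept="icu_id",
    cumulative=ip.CumulativeSpec(mode="phase", basis="constant"),
    smoothing={"baseline": 1.0, "re(icu_id)": 16.0},
)
models = {c: ip.fit(ped, spec(c)) for c in ("death", "discharge")}

diets = ip.make_diets()
late_std, low = diets["late_standard"], diets["exclusively_low"]
for cause, model in models.items():
    hr = ip.hr_curve(model, late_std, low)
    truth = ip.make_ground_truth_hr(cfg, list(late_std.levels), list(low.levels), cause=cause)
    i = int(np.argmin(truth["hr"])) if cause == "death" else int(np.argmax(truth["hr"]))
    print(f"\nlate standard vs exclusively low, {cause}:")
    print(f"  HR on (4,5]            = {hr['hr'].iloc[0]:.3f}  (lag forces exactly 1)")
    print(f"  estimated extreme HR   = {hr['hr'].iloc[i]:.3f} "
          f"[{hr['ci_low'].iloc[i]:.3f}, {hr['ci_high'].iloc[i]:.3f}] "
          f"on ({hr['t_start'].iloc[i]:.0f},{hr['t_end'].iloc[i]:.0f}]")
    print(f"  true HR there          = {truth['hr'].iloc[i]:.3f}")
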