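import math

import numpy as np
import pandas as pd
import pytest

import icupam as ip
from icupam.simulate import (
    LEVEL_STATIONARY,
    N_INTERVALS,
    phase_effect_surface,
    sticky_transition,
)


def _null_effects():
    z = phase_effect_surface(0.0, 0.0)
    return {c: {"II": z.copy(), "III": z.copy()} for c in ("death", "discharge")}


def test_seed_determinism():
    cfg = ip.SimulationConfig(n_patients=60, rng_seed=5)
    a = ip.cohort_to_frames(ip.simulate_cohort(cfg))
    b = ip.cohort_to_frames(ip.simulate_cohort(cfg))
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])


def test_empty_cohort():
    assert ip.simulate_cohort(ip.SimulationConfig(n_patients=0)) == []


def test_zero_hazards_mean_universal_censoring():
    cfg = ip.SimulationConfig(
        n_patients=40,
        rng_seed=3,
        true_log_hazard={
            "death": np.full(N_INTERVALS, -np.inf),
            "discharge": np.full(N_INTERVALS, -np.inf),
        },
        confounder_effects={"death": {}, "discharge": {}},
        icu_sd=0.0,
    )
    patients = ip.simulate_cohort(cfg)
    assert all(p.outcome == "censored" and p.outcome_time == 60.0 for p in patients)


def test_bad_transition_matrix_rejected():
    cfg = ip.SimulationConfig(intake_transition=np.ones((3, 3)))
    with pytest.raises(ip.ConfigError):
        ip.simulate_cohort(cfg)


def test_sampler_rejects_negative_rates():
    with pytest.raises(ValueError):
        ip.daily_event_sampler(np.array([[-0.1, 0.0]]), np.random.default_rng(0))


def test_sampler_no_hazard_censors_at_60():
    cause, t = ip.daily_event_sampler(np.zeros((56, 2)), np.random.default_rng(0))
    assert cause is None and t == 60.0


def test_sampler_event_probability_matches_closed_form():
    # single interval, lambda_death = ln 2: P(event) = 1 - exp(-ln 2) = 0.5
    rng = np.random.default_rng(42)
    lam = np.array([[math.log(2), 0.0]])
    n = 100_000
    events = sum(ip.daily_event_sampler(lam, rng)[0] is not None for _ in range(n))
    assert events / n == pytest.approx(0.5, abs=0.01)


def test_sampler_cause_split_is_proportional():
    rng = np.random.default_rng(43)
    lam = np.array([[0.3, 0.3]])
    causes = [ip.daily_event_sampler(lam, rng)[0] for _ in range(60_000)]
    events = [c for c in causes if c is not None]
    assert len(events) > 0
    frac_death = sum(c == "death" for c in events) / len(events)
    assert frac_death == pytest.approx(0.5, abs=0.015)


def test_sampler_times_fall_inside_event_interval():
    rng = np.random.default_rng(44)
    lam = np.tile([[0.05, 0.1]], (56, 1))
    for _ in range(200):
        cause, t = ip.daily_event_sampler(lam, rng)
        if cause is None:
            assert t == 60.0
        else:
            assert 4.0 < t <= 60.0


def test_ground_truth_identical_diets_give_unit_hr():
    cfg = ip.SimulationConfig()
    hr = ip.make_ground_truth_hr(cfg, ["II"] * 11, ["II"] * 11)
    assert np.all(hr["hr"] == 1.0)


def test_ground_truth_null_surfaces_give_unit_hr():
    cfg = ip.SimulationConfig(true_cumulative_effect=_null_effects())
    hr = ip.make_ground_truth_hr(cfg, ["III"] * 11, ["I"] * 11)
    assert np.all(hr["hr"] == 1.0)


def test_ground_truth_single_exposed_day_step_surface():
    # level-II effect log 0.75 on late days; diet differs only on day #5,
    # whose dynamic window (full MNT: m=5) is t_start in [9, 19)
    eff = _null_effects()
    eff["death"]["II"] = phase_effect_surface(0.0, math.log(0.75))
    cfg = ip.SimulationConfig(true_cumulative_effect=eff)
    diet = ["I"] * 4 + ["II"] + ["I"] * 6
    hr = ip.make_ground_truth_hr(cfg, diet, ["I"] * 11, cause="death")
    affected = (hr["t_start"] >= 9) & (hr["t_start"] < 19)
    assert np.allclose(hr.loc[affected, "hr"], 0.75)
    assert np.all(hr.loc[~affected, "hr"] == 1.0)


def test_ground_truth_full_late_window_reaches_headline_hr():
    cfg = ip.SimulationConfig()
    hr = ip.make_ground_truth_hr(cfg, ["I"] * 4 + ["II"] * 7, ["I"] * 11, cause="death")
    assert hr["hr"].min() == pytest.approx(0.75, abs=1e-12)
    assert hr["hr"].iloc[0] == 1.0  # lag: first interval untouched


def test_event_rates_match_configured_hazards():
    # null effects, no confounder effects, no frailty: the empirical
    # occurrence/exposure rate must converge to the configured hazard
    lam_d, lam_l = 0.015, 0.04
    cfg = ip.SimulationConfig(
        n_patients=4000,
        rng_seed=9,
        true_log_hazard={
            "death": np.full(N_INTERVALS, math.log(lam_d)),
            "discharge": np.full(N_INTERVALS, math.log(lam_l)),
        },
        true_cumulative_effect=_null_effects(),
        confounder_effects={"death": {}, "discharge": {}},
        icu_sd=0.0,
    )
    patients = ip.simulate_cohort(cfg)
    ped = ip.cohort_to_ped(patients)
    exposure = np.exp(ped["offset"]).sum()
    for col, lam in (("d_death", lam_d), ("d_discharge", lam_l)):
        events = ped[col].sum()
        se = math.sqrt(lam / exposure)
        assert events / exposure == pytest.approx(lam, abs=4 * se)


def test_intake_level_mix_matches_stationary_distribution():
    patients = ip.simulate_cohort(ip.SimulationConfig(n_patients=1500, rng_seed=21))
    levels = []
    for p in patients:
        for d in p.intake_days:
            if not d.oral_only:
                levels.append(ip.classify_day(ip.total_protein(d)))
    counts = np.array([levels.count(l) for l in ("I", "II", "III")]) / len(levels)
    assert np.allclose(counts, LEVEL_STATIONARY, atol=0.02)


def test_transition_matrix_is_row_stochastic_with_target_stationary():
    P = sticky_transition()
    assert np.allclose(P.sum(axis=1), 1.0)
    assert np.allclose(LEVEL_STATIONARY @ P, LEVEL_STATIONARY)
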