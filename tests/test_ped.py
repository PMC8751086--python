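import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icupam as ip
from icupam.ped import LagLeadWindow, window_from_mnt


def _patient(t, outcome="hospital_death", levels=None, icu_day=None):
    levels = levels or ["II"] * 11
    n_days = min(11, int(np.ceil(t)))
    days = [
        ip.DietDay(j + 1, {"I": 0.4, "II": 1.0, "III": 1.5}[levels[j]], 0.0)
        for j in range(n_days)
    ]
    return ip.PatientRecord(
        patient_id=7, icu_id=2, age=55, sex="female", bmi=27, apache2=21,
        admission_category="medical", diagnosis="dx3", year=2014,
        days_mv=3, days_pn=1, days_oral=0, days_propofol=2,
        intake_days=days, outcome=outcome, outcome_time=t, icu_discharge_day=icu_day,
    )


def test_grid_validation():
    with pytest.raises(ValueError):
        ip.IntervalGrid(np.array([4.0, 4.0, 5.0]))
    with pytest.raises(ValueError):
        ip.IntervalGrid(np.array([2.0, 5.0]))


def test_split_death_midway_through_interval():
    rows = ip.split_to_ped(_patient(6.5), ip.IntervalGrid())
    assert list(rows["t_start"]) == [4.0, 5.0, 6.0]
    assert np.allclose(rows["offset"], [np.log(1), np.log(1), np.log(0.5)])
    assert list(rows["d_death"]) == [0.0, 0.0, 1.0]
    assert rows["d_discharge"].sum() == 0


def test_split_censored_patient_has_all_zero_indicators():
    rows = ip.split_to_ped(_patient(60.0, outcome="censored"), ip.IntervalGrid())
    assert len(rows) == 56
    assert rows["d_death"].sum() == 0 and rows["d_discharge"].sum() == 0


def test_split_rejects_followup_before_first_cut():
    grid = ip.IntervalGrid(np.array([5.0, 10.0, 60.0]))
    with pytest.raises(ip.ExclusionError):
        ip.split_to_ped(_patient(4.5), grid)


def test_exposure_telescopes_to_time_at_risk(small_cohort):
    grid = ip.IntervalGrid()
    for p in small_cohort[:60]:
        rows = ip.split_to_ped(p, grid)
        assert np.exp(rows["offset"]).sum() == pytest.approx(p.outcome_time - 4.0, abs=1e-9)
        n_events = rows["d_death"].sum() + rows["d_discharge"].sum()
        assert n_events == (0 if p.outcome == "censored" else 1)


def test_dynamic_window_single_mnt_day():
    # MNT on day #1 only: lead 2*1, so day #1 affects t_start in [5, 7)
    m = np.array([1.0] + [-1.0] * 10)
    W = window_from_mnt(m, ip.IntervalGrid(), "dynamic").W
    active = np.flatnonzero(W[:, 0])
    assert list(ip.IntervalGrid().t_start[active]) == [5.0, 6.0]


def test_first_interval_is_never_affected():
    for mode in ("dynamic", "static"):
        W = window_from_mnt(np.arange(1.0, 12.0), ip.IntervalGrid(), mode).W
        assert np.all(W[0] == 0)  # (4,5]: the 4-day lag excludes every diet day


def test_static_window_day11():
    W = window_from_mnt(np.arange(1.0, 12.0), ip.IntervalGrid(), "static").W
    t0 = ip.IntervalGrid().t_start
    assert np.array_equal(np.flatnonzero(W[:, 10]), np.flatnonzero(t0 >= 15.0))


def test_reference_level_diet_has_zero_design():
    window = ip.window_for_diet(ip.IntervalGrid())
    design = ip.build_cumulative_design(window, ["I"] * 11, "phase")
    assert all(np.all(v == 0) for v in design.values())


def test_phase_counts_hand_example():
    # level II on #5..#11, window fully covering late days at t_start 15..18
    window = ip.window_for_diet(ip.IntervalGrid())
    design = ip.build_cumulative_design(window, ["I"] * 4 + ["II"] * 7, "phase")
    t0 = ip.IntervalGrid().t_start
    assert np.all(design["cum_ii_late"][(t0 >= 15) & (t0 < 19)] == 7)
    assert np.all(design["cum_ii_early"] == 0)
    # three late days (#5,#6,#7) are active at t_start = 11
    assert design["cum_ii_late"][t0 == 11.0] == 3


@given(st.lists(st.sampled_from(["I", "II", "III"]), min_size=11, max_size=11))
@settings(derandomize=True, max_examples=40)
def test_surface_and_phase_representations_agree(levels):
    window = ip.window_for_diet(ip.IntervalGrid())
    surf = ip.build_cumulative_design(window, levels, "surface")
    phase = ip.build_cumulative_design(window, levels, "phase")
    assert np.allclose(
        surf["II"].sum(axis=1), phase["cum_ii_early"] + phase["cum_ii_late"]
    )
    assert np.allclose(
        surf["III"].sum(axis=1), phase["cum_iii_early"] + phase["cum_iii_late"]
    )


@given(
    st.lists(st.sampled_from(["I", "II", "III"]), min_size=11, max_size=11),
    st.lists(st.sampled_from(["I", "II", "III"]), min_size=11, max_size=11),
)
@settings(derandomize=True, max_examples=40)
def test_diets_identical_within_window_have_identical_design(diet_a, diet_b):
    window = ip.window_for_diet(ip.IntervalGrid())
    da = ip.build_cumulative_design(window, diet_a, "surface")
    db = ip.build_cumulative_design(window, diet_b, "surface")
    same_day = np.array([a == b for a, b in zip(diet_a, diet_b)])
    unaffected = ~np.any(window.W[:, ~same_day] > 0, axis=1) if (~same_day).any() else np.ones(56, bool)
    for dummy in ("II", "III"):
        assert np.array_equal(da[dummy][unaffected], db[dummy][unaffected])


def test_cohort_ped_icu_mode_ignores_post_discharge_days(small_cohort):
    ped_icu = ip.cohort_to_ped(small_cohort, cause_set="icu")
    discharged = [p for p in small_cohort if p.icu_discharge_day is not None]
    assert discharged, "fixture should contain early ICU discharges"
    for p in discharged[:10]:
        rows = ped_icu[ped_icu["patient_id"] == p.patient_id]
        for j in range(p.icu_discharge_day + 1, 12):
            assert np.all(rows[f"wII_{j}"] == 0) and np.all(rows[f"wIII_{j}"] == 0)


def test_cohort_ped_event_bookkeeping(ped_small, small_cohort):
    n_death = sum(p.outcome == "hospital_death" for p in small_cohort)
    n_disch = sum(p.outcome == "live_discharge" for p in small_cohort)
    assert ped_small["d_death"].sum() == n_death
    assert ped_small["d_discharge"].sum() == n_disch
    per_patient = ped_small.groupby("patient_id")[["d_death", "d_discharge"]].sum()
    assert per_patient.to_numpy().sum(axis=1).max() <= 1
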