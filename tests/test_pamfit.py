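import numpy as np
import pandas as pd
import pytest

import icupam as ip
from icupam.pamfit import DesignBuilder

from conftest import light_spec

COARSE = np.array([4.0, 15.0, 30.0, 60.0])


def _pwc_spec(cause="death", extra=None):
    return ip.ModelSpec(
        cause=cause,
        baseline_type="pwc",
        smooth=[],
        linear=extra or [],
        categorical={},
        random_intercept=None,
        cumulative=None,
        smoothing={"default": 0.0},
    )


@pytest.fixture(scope="module")
def coarse_ped(small_cohort):
    return ip.cohort_to_ped(small_cohort[:50], ip.IntervalGrid(COARSE))


def test_single_interval_fit_recovers_occurrence_exposure(small_cohort):
    grid = ip.IntervalGrid(np.array([4.0, 60.0]))
    ped = ip.cohort_to_ped(small_cohort[:50], grid)
    model = ip.fit(ped, _pwc_spec())
    rate = ped["d_death"].sum() / np.exp(ped["offset"]).sum()
    assert np.exp(model.beta[0]) == pytest.approx(rate, rel=1e-8)


def test_saturated_fit_matches_per_interval_rates(coarse_ped):
    """Unpenalized covariate-free fit = events/person-time in every interval."""
    for cause in ("death", "discharge"):
        model = ip.fit(coarse_ped, _pwc_spec(cause))
        agg = coarse_ped.assign(exposure=np.exp(coarse_ped["offset"])).groupby("interval")
        events = agg[f"d_{cause}"].sum().to_numpy()
        exposure = agg["exposure"].sum().to_numpy()
        assert np.all(events > 0), "fixture must have events in every coarse interval"
        fitted = np.exp(model.beta[: len(events)])
        assert np.max(np.abs(fitted / (events / exposure) - 1.0)) < 1e-6


def test_row_duplication_invariance(coarse_ped):
    model_a = ip.fit(coarse_ped, _pwc_spec(extra=["age"]))
    # split each pseudo-observation into two half-exposure rows, the event
    # indicator staying on one copy: the Poisson likelihood is unchanged
    copy = coarse_ped.copy()
    copy[["d_death", "d_discharge"]] = 0.0
    doubled = pd.concat([coarse_ped, copy], ignore_index=True)
    doubled["offset"] -= np.log(2.0)
    doubled.attrs.update(coarse_ped.attrs)
    model_b = ip.fit(doubled, _pwc_spec(extra=["age"]))
    assert np.allclose(model_a.beta, model_b.beta, atol=1e-7)


def _survival_loglik(model, patients, grid):
    """Independent piece-wise exponential survival log-likelihood
    sum_i [delta_i log lambda(t_i) - Lambda(t_i)], evaluated directly."""
    total = 0.0
    for p in patients:
        rows = ip.split_to_ped(p, grid)
        traj = ip.build_trajectory(p)
        window = ip.build_window(traj, grid)
        levels = [d.level for d in traj]
        design = ip.build_cumulative_design(
            ip.LagLeadWindow(W=window.W[rows["interval"].to_numpy()], mode="dynamic"),
            levels,
            "phase",
        )
        df = rows.copy()
        for k, v in design.items():
            df[k] = v
        for f in ("age", "apache2", "icu_id"):
            df[f] = getattr(p, f)
        eta = model.linear_predictor(df)
        lam = np.exp(eta)
        exposure = np.exp(df["offset"].to_numpy())
        total -= float(lam @ exposure)  # -Lambda(t_i)
        # cause-specific death model: only death events contribute log lambda
        if df["d_death"].iloc[-1] == 1:
            total += float(eta[-1])
    return total


def test_poisson_and_survival_loglik_agree_up_to_constant(tiny_fixture_cohort):
    grid = ip.IntervalGrid()
    ped = ip.cohort_to_ped(tiny_fixture_cohort, grid)
    model = ip.fit(ped, light_spec("death"))
    const = [
        ip.loglik(model, ped) - _survival_loglik(model, tiny_fixture_cohort, grid)
    ]
    # perturbing beta must leave the difference (a beta-independent constant)
    model.beta = model.beta + 0.1
    const.append(ip.loglik(model, ped) - _survival_loglik(model, tiny_fixture_cohort, grid))
    assert const[0] == pytest.approx(const[1], abs=1e-8)
    # the constant is sum over events of log(final-interval exposure)
    expected = sum(
        np.log(min(p.outcome_time, 60) - np.floor(p.outcome_time))
        if p.outcome_time != np.floor(p.outcome_time) else 0.0
        for p in tiny_fixture_cohort if p.outcome != "censored" and p.outcome == "hospital_death"
    )
    assert const[0] == pytest.approx(expected, abs=1e-8)


def test_less_penalty_weakly_increases_loglik(ped_small):
    strong = ip.fit(ped_small, light_spec("death", {"baseline": 100.0, "re(icu_id)": 100.0}))
    weak = ip.fit(ped_small, light_spec("death", {"baseline": 1e-4, "re(icu_id)": 1e-4}))
    assert weak.loglik >= strong.loglik - 1e-6


def test_matches_statsmodels_glm(coarse_ped):
    """Independent oracle: unpenalized Poisson GLM with offset."""
    import statsmodels.api as sm

    spec = _pwc_spec(extra=["age", "apache2"])
    model = ip.fit(coarse_ped, spec)
    X = DesignBuilder(spec, COARSE).fit(coarse_ped)
    glm = sm.GLM(
        coarse_ped["d_death"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
        offset=coarse_ped["offset"].to_numpy(dtype=float),
    ).fit()
    assert np.allclose(model.beta, glm.params, atol=1e-6)


def test_diet_contrast_is_confounder_free(fitted_models):
    """Two predictions differing only in diet give an eta difference that is
    the same at any confounder value (additivity)."""
    model = fitted_models["death"]
    grid = ip.IntervalGrid(model.grid_cuts)
    from icupam.effects import _diet_frame, make_diets

    diets = make_diets()
    df_a = _diet_frame(diets["early_standard"], grid, "dynamic")
    df_b = _diet_frame(diets["exclusively_low"], grid, "dynamic")
    base = model.linear_predictor(df_a, population=True) - model.linear_predictor(
        df_b, population=True
    )
    for age in (30.0, 80.0):
        shifted = base.copy()
        da, db = df_a.assign(age=age, apache2=35.0), df_b.assign(age=age, apache2=35.0)
        diff = model.linear_predictor(da, population=True) - model.linear_predictor(
            db, population=True
        )
        assert np.allclose(diff, shifted, atol=1e-10)


def test_reference_profile_prediction_is_baseline(fitted_models):
    """At the population-average profile with an all-level-I diet, the
    linear predictor equals intercept + baseline smooth, re-evaluated here
    directly from the B-spline basis."""
    from icupam.effects import _diet_frame, make_diets
    from icupam.splines import bspline_design

    model = fitted_models["death"]
    grid = ip.IntervalGrid(model.grid_cuts)
    df = _diet_frame(make_diets()["exclusively_low"], grid, "dynamic")
    eta, _ = model.predict_log_hazard(df, population=True)
    blk = next(b for b in model.builder.blocks if b["name"] == "baseline")
    B = bspline_design(grid.t_mid, blk["xmin"], blk["xmax"], blk["k"], blk["degree"])
    sl = model.builder.block_slice("baseline")
    expected = model.beta[0] + (B @ blk["Z"]) @ model.beta[sl]
    np.testing.assert_allclose(eta, expected, atol=1e-12)


def test_prediction_se_nonnegative(fitted_models):
    model = fitted_models["death"]
    from icupam.effects import _diet_frame, make_diets

    df = _diet_frame(make_diets()["early_standard"], ip.IntervalGrid(model.grid_cuts), "dynamic")
    _, se = model.predict_log_hazard(df)
    assert np.all(se >= 0)


def test_serialization_roundtrip(fitted_models, tmp_path):
    model = fitted_models["discharge"]
    path = tmp_path / "model.json"
    model.save(path)
    loaded = ip.FittedHazardModel.load(path)
    from icupam.effects import _diet_frame, make_diets

    df = _diet_frame(make_diets()["late_standard"], ip.IntervalGrid(model.grid_cuts), "dynamic")
    np.testing.assert_allclose(
        model.predict_log_hazard(df)[0], loaded.predict_log_hazard(df)[0]
    )
    np.testing.assert_allclose(
        model.predict_log_hazard(df)[1], loaded.predict_log_hazard(df)[1]
    )
    assert loaded.lam == model.lam


def test_reml_smoothing_selection_runs(ped_small):
    spec = ip.ModelSpec(
        cause="death",
        baseline_type="ps",
        baseline_k=8,
        linear=["age"],
        random_intercept=None,
        cumulative=ip.CumulativeSpec(mode="phase", basis="constant"),
        smoothing="reml",
    )
    model = ip.fit(ped_small, spec)
    assert model.converged
    assert all(np.isfinite(v) and v > 0 for v in model.lam.values())
    # with one penalized smooth, edf must lie between a line and the full basis
    assert 2 < model.edf < 8 + 4 + 2


def test_surface_mode_fits_and_contrasts(ped_small):
    spec = ip.ModelSpec(
        cause="death",
        baseline_type="ps",
        baseline_k=6,
        linear=["age"],
        random_intercept=None,
        cumulative=ip.CumulativeSpec(mode="surface", k_t=4, k_z=4),
        smoothing={"default": 1.0},
    )
    model = ip.fit(ped_small, spec)
    diets = ip.make_diets()
    hr = ip.hr_curve(model, diets["late_standard"], diets["exclusively_low"])
    assert hr["hr"].iloc[0] == 1.0
    assert np.all(hr["ci_low"] <= hr["hr"]) and np.all(hr["hr"] <= hr["ci_high"])


def test_recovery_on_known_truth(recovery_fit):
    """On a large synthetic cohort with a known late level-II death effect,
    the estimated late-standard-vs-low HR curve covers the truth."""
    cfg, model = recovery_fit
    diets = ip.make_diets()
    hr = ip.hr_curve(model, diets["late_standard"], diets["exclusively_low"])
    truth = ip.make_ground_truth_hr(
        cfg, list(diets["late_standard"].levels), list(diets["exclusively_low"].levels)
    )["hr"].to_numpy()
    nz = truth != 1.0
    covered = (hr["ci_low"].to_numpy()[nz] <= truth[nz]) & (
        truth[nz] <= hr["ci_high"].to_numpy()[nz]
    )
    assert covered.mean() > 0.8
    i_min = int(np.argmin(truth))
    assert hr["ci_low"].iloc[i_min] <= 0.75 <= hr["ci_high"].iloc[i_min]
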