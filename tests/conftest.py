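import numpy as np
import pytest

import icupam as ip


def light_spec(cause: str, smoothing=None) -> ip.ModelSpec:
    """Small adjusted model used throughout the tests: P-spline baseline,
    linear age + APACHE II, ICU ridge intercept, constant phase-mode
    cumulative coefficients, fixed smoothing for bit-for-bit results."""
    return ip.ModelSpec(
        cause=cause,
        baseline_type="ps",
        baseline_k=8,
        linear=["age", "apache2"],
        random_intercept="icu_id",
        cumulative=ip.CumulativeSpec(mode="phase", basis="constant"),
        smoothing=smoothing or {"baseline": 1.0, "re(icu_id)": 16.0},
    )


@pytest.fixture(scope="session")
def small_cohort():
    return ip.simulate_cohort(ip.SimulationConfig(n_patients=250, rng_seed=11))


@pytest.fixture(scope="session")
def ped_small(small_cohort):
    return ip.cohort_to_ped(small_cohort)


@pytest.fixture(scope="session")
def fitted_models(ped_small):
    return {cause: ip.fit(ped_small, light_spec(cause)) for cause in ("death", "discharge")}


@pytest.fixture(scope="session")
def recovery_fit():
    """One n=2000 cohort under the default known-truth scenario with its
    fitted death model, shared by the parameter-recovery checks."""
    cfg = ip.SimulationConfig(n_patients=2000, rng_seed=2000)
    patients = ip.simulate_cohort(cfg)
    ped = ip.cohort_to_ped(patients)
    model = ip.fit(ped, light_spec("death"))
    return cfg, model


@pytest.fixture(scope="session")
def tiny_fixture_cohort():
    """Five hand-checkable patients used by the likelihood-identity checks."""
    def mk(pid, outcome, t, levels):
        days = [
            ip.DietDay(j + 1, {"I": 0.4, "II": 1.0, "III": 1.5}[lv], 0.0)
            for j, lv in enumerate(levels)
        ]
        return ip.PatientRecord(
            patient_id=pid, icu_id=pid % 2, age=60 + pid, sex="female", bmi=25.0,
            apache2=20.0 + pid, admission_category="medical", diagnosis="dx1",
            year=2013, days_mv=2, days_pn=0, days_oral=0, days_propofol=1,
            intake_days=days, outcome=outcome, outcome_time=t,
        )

    return [
        mk(0, "hospital_death", 6.5, ["I"] * 7),
        mk(1, "live_discharge", 12.25, ["II"] * 11),
        mk(2, "censored", 60.0, ["III"] * 11),
        mk(3, "hospital_death", 30.0, ["I"] * 4 + ["II"] * 7),
        mk(4, "live_discharge", 8.75, ["II"] * 4 + ["I"] * 5),
    ]
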