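"""Piece-wise exponential data (PED) and lag-lead exposure windows.

Follow-up beyond day 4 after ICU admission is split into intervals (a, b];
each patient contributes one pseudo-observation per interval at risk, with a
log person-time offset and one event indicator per competing cause
(in-hospital death, live hospital discharge). On this representation the
piece-wise exponential model is an ordinary Poisson regression.

A day on diet t_z may affect the hazard of interval (t, t+1] only inside a
lag-lead window: the lag is 4 days (guarding against indication bias); the
lead is twice the cumulative number of days with medical nutrition therapy
(dynamic mode) or 60 days (static sensitivity mode). The window indicator
compares against the interval's *left* endpoint, so the first interval
(4, 5] is structurally unaffected by any diet day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .exceptions import ExclusionError
from .intake import DailyIntake, build_trajectory

LAG_DAYS = 4
STATIC_LEAD_DAYS = 60
N_DIET_DAYS = 11
EARLY_DAYS = 4  # days on diet #1..#4 constitute the early acute phase

#: Names of the phase-mode cumulative design columns: weighted counts of
#: window-active days at each level (vs the level-I reference), split into
#: early (#1-#4) and late (#5-#11) acute phase.
PHASE_COLUMNS = ("cum_ii_early", "cum_ii_late", "cum_iii_early", "cum_iii_late")


@dataclass
class IntervalGrid:
    """Partition of follow-up into half-open intervals (a, b].

    The default is daily from day 4 to day 60 (56 intervals). The first cut
    must be >= 4 because inclusion conditions on 96 h of ICU survival.
    """

    cuts: np.ndarray = field(default_factory=lambda: np.arange(4.0, 61.0))

    def __post_init__(self):
        self.cuts = np.asarray(self.cuts, dtype=float)
        if self.cuts.ndim != 1 or len(self.cuts) < 2:
            raise ValueError("grid needs at least two cut points")
        if np.any(np.diff(self.cuts) <= 0):
            raise ValueError("cut points must be strictly increasing")
        if self.cuts[0] < 4:
            raise ValueError("first cut point must be >= 4 (96-h inclusion)")

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) - 1

    @property
    def t_start(self) -> np.ndarray:
        return self.cuts[:-1]

    @property
    def t_end(self) -> np.ndarray:
        return self.cuts[1:]

    @property
    def t_mid(self) -> np.ndarray:
        return 0.5 * (self.cuts[:-1] + self.cuts[1:])


@dataclass
class LagLeadWindow:
    """Indicator W[interval, day] of which diet days can move which hazards."""

    W: np.ndarray  # (n_intervals, 11) of {0, 1}
    mode: str


def window_from_mnt(m: np.ndarray, grid: IntervalGrid, mode: str = "dynamic") -> LagLeadWindow:
    """Window from the cumulative MNT-day count m(t_z), t_z = 1..11.

    Dynamic: W = 1 iff t_start >= t_z + 4 and t_start < t_z + 4 + 2 m(t_z).
    Static: W = 1 iff t_z + 4 <= t_start < t_z + 4 + 60.
    Days beyond the recorded trajectory (m entries of -1) never activate.
    """
    if mode not in ("dynamic", "static"):
        raise ValueError(f"unknown window mode {mode!r}")
    m = np.asarray(m, dtype=float)
    if m.shape != (N_DIET_DAYS,):
        raise ValueError("m must have one entry per day on diet #1..#11")
    t0 = grid.t_start[:, None]  # (n_int, 1)
    tz = np.arange(1, N_DIET_DAYS + 1)[None, :]  # (1, 11)
    lower = tz + LAG_DAYS
    lead = 2.0 * m[None, :] if mode == "dynamic" else float(STATIC_LEAD_DAYS)
    W = (t0 >= lower) & (t0 < lower + lead) & (m[None, :] >= 0)
    return LagLeadWindow(W=W.astype(float), mode=mode)


def build_window(
    trajectory: list[DailyIntake], grid: IntervalGrid, mode: str = "dynamic"
) -> LagLeadWindow:
    """Lag-lead window for an observed (possibly imputed) trajectory.

    m(t_z) counts days with any EN/PN intake up to and including t_z;
    imputed post-ICU days count as MNT days.
    """
    m = np.full(N_DIET_DAYS, -1.0)
    cum = 0
    for d in trajectory:
        cum += int(d.mnt)
        m[d.day_index - 1] = cum
    return window_from_mnt(m, grid, mode)


def window_for_diet(grid: IntervalGrid, mode: str = "dynamic") -> LagLeadWindow:
    """Window for a hypothetical diet: MNT on every day, so m(t_z) = t_z."""
    return window_from_mnt(np.arange(1, N_DIET_DAYS + 1, dtype=float), grid, mode)


def level_dummies(levels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(II, III) indicator vectors over days #1..#11; short lists are padded
    with the reference level (absent days cannot activate anyway)."""
    lv = list(levels) + ["I"] * (N_DIET_DAYS - len(levels))
    d2 = np.array([1.0 if l == "II" else 0.0 for l in lv])
    d3 = np.array([1.0 if l == "III" else 0.0 for l in lv])
    return d2, d3


def build_cumulative_design(
    window: LagLeadWindow, trajectory_levels: list[str], basis_mode: str = "phase"
):
    """Per-interval cumulative-effect design entries.

    ``phase``: four weighted counts per interval (level II/III crossed with
    early/late acute phase). ``surface``: per-dummy (n_intervals x 11)
    matrices of active-day indicators, to be contracted against a smooth
    surface basis g(t, t_z) downstream. The phase counts are exactly the
    phase-wise row sums of the surface matrices.
    """
    d2, d3 = level_dummies(trajectory_levels)
    W = window.W
    if basis_mode == "surface":
        return {"II": W * d2[None, :], "III": W * d3[None, :]}
    if basis_mode == "phase":
        early = slice(0, EARLY_DAYS)
        late = slice(EARLY_DAYS, N_DIET_DAYS)
        return {
            "cum_ii_early": (W[:, early] * d2[None, early]).sum(axis=1),
            "cum_ii_late": (W[:, late] * d2[None, late]).sum(axis=1),
            "cum_iii_early": (W[:, early] * d3[None, early]).sum(axis=1),
            "cum_iii_late": (W[:, late] * d3[None, late]).sum(axis=1),
        }
    raise ValueError(f"unknown basis mode {basis_mode!r}")


def _event_for_cause_set(patient: PatientRecord, cause_set: str) -> tuple[str | None, float]:
    """Map the recorded hospital outcome to the requested competing-risk pair.

    ``hospital``: outcomes as recorded. ``icu``: live ICU discharge before
    the hospital outcome becomes the discharge event (competing risk),
    censoring the later hospital course; otherwise the hospital outcome
    stands in for the ICU outcome (death in ICU, or discharge/censoring
    while still in the ICU).
    """
    if cause_set == "hospital":
        cause = {"hospital_death": "death", "live_discharge": "discharge", "censored": None}[
            patient.outcome
        ]
        return cause, patient.outcome_time
    if cause_set == "icu":
        if patient.icu_discharge_day is not None and patient.icu_discharge_day < patient.outcome_time:
            return "discharge", float(patient.icu_discharge_day)
        cause = {"hospital_death": "death", "live_discharge": "discharge", "censored": None}[
            patient.outcome
        ]
        return cause, patient.outcome_time
    raise ValueError(f"unknown cause set {cause_set!r}")


def split_to_ped(
    patient: PatientRecord, grid: IntervalGrid, cause_set: str = "hospital"
) -> pd.DataFrame:
    """One patient's PED rows: interval bounds, log-exposure offset, and the
    two cause-specific event indicators (at most one is 1, in the last row).
    """
    cause, time = _event_for_cause_set(patient, cause_set)
    if time <= grid.cuts[0]:
        raise ExclusionError(
            f"patient {patient.patient_id}: follow-up {time} does not exceed "
            f"day {grid.cuts[0]} (violates inclusion criteria)"
        )
    t0, t1 = grid.t_start, grid.t_end
    at_risk = t0 < time
    idx = np.flatnonzero(at_risk)
    end = np.minimum(t1[idx], time)
    exposure = end - t0[idx]
    d_death = np.zeros(len(idx))
    d_discharge = np.zeros(len(idx))
    if cause is not None and time <= grid.cuts[-1]:
        if cause == "death":
            d_death[-1] = 1.0
        else:
            d_discharge[-1] = 1.0
    return pd.DataFrame(
        {
            "patient_id": patient.patient_id,
            "interval": idx,
            "t_start": t0[idx],
            "t_end": t1[idx],
            "t_mid": grid.t_mid[idx],
            "offset": np.log(exposure),
            "d_death": d_death,
            "d_discharge": d_discharge,
        }
    )


_CONFOUNDER_FIELDS = (
    "icu_id",
    "age",
    "sex",
    "bmi",
    "apache2",
    "admission_category",
    "diagnosis",
    "year",
    "days_mv",
    "days_pn",
    "days_oral",
    "days_propofol",
)


def cohort_to_ped(
    patients: list[PatientRecord],
    grid: IntervalGrid | None = None,
    cause_set: str = "hospital",
    window_mode: str = "dynamic",
) -> pd.DataFrame:
    """Full PED table for a cohort: split rows, confounders, window columns
    (wII_j / wIII_j = window indicator times level dummy for day #j) and the
    four phase-mode cumulative counts.

    The intake trajectory is built in hospital mode (with imputation) for
    hospital outcomes and in icu mode (truncated, never imputed) for ICU
    outcomes, so the sensitivity analysis makes no post-discharge intake
    assumption.
    """
    grid = grid or IntervalGrid()
    traj_mode = "hospital" if cause_set == "hospital" else "icu"
    t0g, t1g, tmg = grid.t_start, grid.t_end, grid.t_mid
    num_parts, w2_parts, w3_parts, conf_rows = [], [], [], []
    for p in patients:
        cause, time = _event_for_cause_set(p, cause_set)
        if time <= grid.cuts[0]:
            raise ExclusionError(
                f"patient {p.patient_id}: follow-up {time} does not exceed "
                f"day {grid.cuts[0]} (violates inclusion criteria)"
            )
        idx = np.flatnonzero(t0g < time)
        nrow = len(idx)
        exposure = np.minimum(t1g[idx], time) - t0g[idx]
        d_death = np.zeros(nrow)
        d_discharge = np.zeros(nrow)
        if cause is not None and time <= grid.cuts[-1]:
            (d_death if cause == "death" else d_discharge)[-1] = 1.0
        traj = build_trajectory(p, mode=traj_mode)
        window = build_window(traj, grid, window_mode)
        levels = [d.level for d in traj]
        d2, d3 = level_dummies(levels)
        Wsub = window.W[idx]
        num_parts.append(
            np.column_stack(
                [
                    np.full(nrow, p.patient_id, dtype=float),
                    idx.astype(float),
                    t0g[idx],
                    t1g[idx],
                    tmg[idx],
                    np.log(exposure),
                    d_death,
                    d_discharge,
                ]
            )
        )
        w2_parts.append(Wsub * d2[None, :])
        w3_parts.append(Wsub * d3[None, :])
        conf_rows.append([nrow] + [getattr(p, f) for f in _CONFOUNDER_FIELDS])
    num = np.vstack(num_parts)
    w2 = np.vstack(w2_parts)
    w3 = np.vstack(w3_parts)
    ped = pd.DataFrame(
        num,
        columns=["patient_id", "interval", "t_start", "t_end", "t_mid", "offset",
                 "d_death", "d_discharge"],
    )
    ped["patient_id"] = ped["patient_id"].astype(int)
    ped["interval"] = ped["interval"].astype(int)
    for j in range(N_DIET_DAYS):
        ped[f"wII_{j + 1}"] = w2[:, j]
        ped[f"wIII_{j + 1}"] = w3[:, j]
    early, late = slice(0, EARLY_DAYS), slice(EARLY_DAYS, N_DIET_DAYS)
    ped["cum_ii_early"] = w2[:, early].sum(axis=1)
    ped["cum_ii_late"] = w2[:, late].sum(axis=1)
    ped["cum_iii_early"] = w3[:, early].sum(axis=1)
    ped["cum_iii_late"] = w3[:, late].sum(axis=1)
    reps = np.concatenate([np.full(r[0], i) for i, r in enumerate(conf_rows)])
    for k, f in enumerate(_CONFOUNDER_FIELDS, start=1):
        vals = np.array([r[k] for r in conf_rows], dtype=object)[reps]
        ped[f] = pd.array(vals.tolist())
    ped.attrs["grid_cuts"] = grid.cuts.tolist()
    ped.attrs["cause_set"] = cause_set
    ped.attrs["window_mode"] = window_mode
    return ped
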