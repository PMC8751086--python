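"""Daily protein intake: quantification, level classification, imputation.

Total daily protein (g/kg) is enteral protein plus parenteral amino acids
converted to protein-equivalent with the factor 0.83. Days are classified
into three established intake levels:

* level I (low): < 0.8 g/kg per day,
* level II (standard): 0.8-1.2 g/kg per day (both boundaries included),
* level III (high): > 1.2 g/kg per day.

Days with exclusively oral intake count as level I regardless of amount.
For the hospital-outcome analysis, surviving patients discharged alive from
the ICU before day on diet #11 have the remaining days imputed as standard
(level II) intake; the ICU-outcome sensitivity analysis instead truncates
the trajectory at ICU discharge and never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import DietDay, PatientRecord
from .exceptions import MissingIntakeError

#: Protein-equivalent grams per gram of parenteral amino acids.
PN_TO_PROTEIN = 0.83

#: Level bounds in g/kg per day (level II is the closed interval).
LEVEL_II_LOW = 0.8
LEVEL_II_HIGH = 1.2

#: Cohort-level median intake per level, g/kg per day. The level-II median
#: doubles as the numeric placeholder carried by imputed days (the model
#: consumes the category, not the number).
LEVEL_MEDIANS = {"I": 0.49, "II": 0.99, "III": 1.41}

LEVELS = ("I", "II", "III")


@dataclass
class DailyIntake:
    """Classified daily intake; ``imputed`` marks post-ICU-discharge fills."""

    day_index: int
    total_protein: float
    level: str
    imputed: bool = False
    oral_only: bool = False
    mnt: bool = True  # received enteral and/or parenteral nutrition that day


def total_protein(day: DietDay) -> float:
    """Protein-equivalent daily intake in g/kg.

    Oral-only days contribute nothing (oral protein is ignored throughout).
    """
    if day.en_protein < 0 or day.pn_amino_acids < 0:
        raise ValueError("intake amounts must be nonnegative")
    if day.oral_only:
        return 0.0
    return day.en_protein + PN_TO_PROTEIN * day.pn_amino_acids


def classify_day(total: float, oral_only: bool = False) -> str:
    """Map a daily total (g/kg) to level I/II/III; oral-only days are level I."""
    if total < 0:
        raise ValueError("total intake must be nonnegative")
    if oral_only:
        return "I"
    if total < LEVEL_II_LOW:
        return "I"
    if total <= LEVEL_II_HIGH:
        return "II"
    return "III"


def build_trajectory(patient: PatientRecord, mode: str = "hospital") -> list[DailyIntake]:
    """Classified day-on-diet trajectory for one patient.

    Parameters
    ----------
    patient
        Record whose ``intake_days`` hold the observed days (contiguous from
        day #1; registration stops at ICU discharge, death, or day #11).
    mode
        ``"hospital"`` — days between live ICU discharge and day #11 are
        filled with imputed level-II days while the patient is alive;
        ``"icu"`` — observed days only, no imputation.

    Imputed days count as days with medical nutrition therapy (MNT) in
    hospital mode, so they extend the dynamic lead time. Days after death
    are never filled.
    """
    if mode not in ("hospital", "icu"):
        raise ValueError(f"unknown mode {mode!r}")
    observed = [d.day_index for d in patient.intake_days]
    if observed != list(range(1, len(observed) + 1)):
        raise MissingIntakeError(
            f"patient {patient.patient_id}: intake days {observed} are not "
            "contiguous from day #1"
        )
    traj: list[DailyIntake] = []
    for d in patient.intake_days:
        tot = total_protein(d)
        traj.append(
            DailyIntake(
                day_index=d.day_index,
                total_protein=tot,
                level=classify_day(tot, d.oral_only),
                imputed=False,
                oral_only=d.oral_only,
                mnt=(not d.oral_only) and tot > 0,
            )
        )
    if mode == "icu":
        return traj
    if patient.icu_discharge_day is None:
        return traj
    last = len(traj)
    if last < patient.icu_discharge_day:
        raise MissingIntakeError(
            f"patient {patient.patient_id}: recorded intake ends on day #{last} "
            f"before ICU discharge on day #{patient.icu_discharge_day}"
        )
    for j in range(last + 1, 12):
        if j - 1 >= patient.outcome_time:  # day j never started: patient dead/gone
            break
        traj.append(
            DailyIntake(
                day_index=j,
                total_protein=LEVEL_MEDIANS["II"],
                level="II",
                imputed=True,
                oral_only=False,
                mnt=True,
            )
        )
    return traj
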