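"""Patient-level data containers and the two-table CSV schema.

The analysis consumes two tables:

* an **admission table** with one row per patient (covariates measured at or
  shortly after ICU admission, the competing outcome and its time), and
* a **patient-day table** with one row per recorded day on diet (#1..#11)
  holding enteral protein and parenteral amino-acid intake in g/kg.

Both tables are plain CSV; the schema is version-stamped via
:data:`SCHEMA_VERSION` and validated on read with row-level error reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

SCHEMA_VERSION = "1.0"

#: Admission-level outcome labels. ``censored`` means alive and still in
#: hospital at the 60-day administrative censoring horizon.
OUTCOMES = ("hospital_death", "live_discharge", "censored")

ADMISSION_COLUMNS = [
    "patient_id",
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
    "outcome",
    "outcome_time",
    "icu_discharge_day",
    "calorie_fraction",
]

PATIENT_DAY_COLUMNS = [
    "patient_id",
    "day_index",
    "en_protein_gkg",
    "pn_amino_gkg",
    "oral_only",
]

ADMISSION_CATEGORIES = ("elective surgery", "emergency surgery", "medical")


@dataclass
class DietDay:
    """One recorded day on diet (#1..#11).

    ``en_protein`` is enteral protein in g/kg; ``pn_amino_acids`` is
    parenteral amino-acid intake in g/kg (converted to protein-equivalent
    downstream). ``oral_only`` marks days on which the patient received
    nutrition exclusively by mouth; such days carry no EN/PN amounts.
    """

    day_index: int
    en_protein: float
    pn_amino_acids: float
    oral_only: bool = False

    def __post_init__(self):
        if not 1 <= self.day_index <= 11:
            raise ValueError(f"day_index must be in 1..11, got {self.day_index}")
        if self.en_protein < 0 or self.pn_amino_acids < 0:
            raise ValueError("intake amounts must be nonnegative")
        if self.oral_only and (self.en_protein != 0 or self.pn_amino_acids != 0):
            raise ValueError("oral-only days must have zero EN/PN intake")


@dataclass
class PatientRecord:
    """One admission: covariates, intake trajectory and competing outcome.

    ``outcome_time`` is continuous days after ICU admission (24-h clock from
    the admission timestamp) and always exceeds 4 because inclusion requires
    at least 96 h of ICU treatment. ``icu_discharge_day`` is set only when
    the patient was discharged alive from the ICU *before* day on diet #11
    while remaining in hospital — exactly the case that triggers protein
    imputation in the hospital-outcome analysis.
    """

    patient_id: int
    icu_id: int
    age: float
    sex: str
    bmi: float
    apache2: float
    admission_category: str
    diagnosis: str
    year: int
    days_mv: int
    days_pn: int
    days_oral: int
    days_propofol: int
    intake_days: list[DietDay] = field(default_factory=list)
    outcome: str = "censored"
    outcome_time: float = 60.0
    icu_discharge_day: int | None = None
    calorie_fraction: float | None = None

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome_time <= 4:
            raise ValueError("outcome_time must exceed 4 days (96-h inclusion)")
        if self.outcome == "censored" and self.outcome_time != 60:
            raise ValueError("censored patients must have outcome_time == 60")
        days = [d.day_index for d in self.intake_days]
        if days != list(range(1, len(days) + 1)):
            raise ValueError("intake_days must be contiguous starting at day #1")


def cohort_to_frames(patients: list[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (admission table, patient-day table)."""
    adm_rows, day_rows = [], []
    for p in patients:
        adm_rows.append(
            {
                "patient_id": p.patient_id,
                "icu_id": p.icu_id,
                "age": p.age,
                "sex": p.sex,
                "bmi": p.bmi,
                "apache2": p.apache2,
                "admission_category": p.admission_category,
                "diagnosis": p.diagnosis,
                "year": p.year,
                "days_mv": p.days_mv,
                "days_pn": p.days_pn,
                "days_oral": p.days_oral,
                "days_propofol": p.days_propofol,
                "outcome": p.outcome,
                "outcome_time": p.outcome_time,
                "icu_discharge_day": p.icu_discharge_day,
                "calorie_fraction": p.calorie_fraction,
            }
        )
        for d in p.intake_days:
            day_rows.append(
                {
                    "patient_id": p.patient_id,
                    "day_index": d.day_index,
                    "en_protein_gkg": d.en_protein,
                    "pn_amino_gkg": d.pn_amino_acids,
                    "oral_only": int(d.oral_only),
                }
            )
    adm = pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS)
    days = pd.DataFrame(day_rows, columns=PATIENT_DAY_COLUMNS)
    return adm, days


def frames_to_cohort(adm: pd.DataFrame, days: pd.DataFrame) -> list[PatientRecord]:
    """Validate the two tables and rebuild :class:`PatientRecord` objects.

    Malformed rows are collected and reported together with their row
    numbers; nothing is silently repaired.
    """
    problems: list[str] = []
    for col in ADMISSION_COLUMNS:
        if col not in adm.columns:
            problems.append(f"admission table: missing column {col!r}")
    for col in PATIENT_DAY_COLUMNS:
        if col not in days.columns:
            problems.append(f"patient-day table: missing column {col!r}")
    if problems:
        raise SchemaError("; ".join(problems))

    day_groups: dict[int, list[DietDay]] = {}
    for i, row in days.iterrows():
        try:
            dd = DietDay(
                day_index=int(row["day_index"]),
                en_protein=float(row["en_protein_gkg"]),
                pn_amino_acids=float(row["pn_amino_gkg"]),
                oral_only=bool(row["oral_only"]),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"patient-day row {i}: {exc}")
            continue
        day_groups.setdefault(int(row["patient_id"]), []).append(dd)

    patients: list[PatientRecord] = []
    for i, row in adm.iterrows():
        icu_d = row["icu_discharge_day"]
        icu_d = None if pd.isna(icu_d) else int(icu_d)
        cf = row["calorie_fraction"]
        cf = None if pd.isna(cf) else float(cf)
        if cf is not None and (cf < 0 or not math.isfinite(cf)):
            problems.append(f"admission row {i}: calorie_fraction must be finite and >= 0")
            continue
        intake = sorted(day_groups.get(int(row["patient_id"]), []), key=lambda d: d.day_index)
        try:
            patients.append(
                PatientRecord(
                    patient_id=int(row["patient_id"]),
                    icu_id=int(row["icu_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    bmi=float(row["bmi"]),
                    apache2=float(row["apache2"]),
                    admission_category=str(row["admission_category"]),
                    diagnosis=str(row["diagnosis"]),
                    year=int(row["year"]),
                    days_mv=int(row["days_mv"]),
                    days_pn=int(row["days_pn"]),
                    days_oral=int(row["days_oral"]),
                    days_propofol=int(row["days_propofol"]),
                    intake_days=intake,
                    outcome=str(row["outcome"]),
                    outcome_time=float(row["outcome_time"]),
                    icu_discharge_day=icu_d,
                    calorie_fraction=cf,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"admission row {i}: {exc}")
    if problems:
        raise SchemaError("; ".join(problems))
    return patients


def write_cohort(patients: list[PatientRecord], outdir: str | Path) -> tuple[Path, Path]:
    """Write ``admissions.csv`` and ``patient_days.csv`` under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adm, days = cohort_to_frames(patients)
    adm_path = outdir / "admissions.csv"
    day_path = outdir / "patient_days.csv"
    adm.to_csv(adm_path, index=False)
    days.to_csv(day_path, index=False)
    return adm_path, day_path


def read_cohort(admissions_csv: str | Path, patient_days_csv: str | Path) -> list[PatientRecord]:
    adm = pd.read_csv(admissions_csv)
    days = pd.read_csv(patient_days_csv)
    return frames_to_cohort(adm, days)
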