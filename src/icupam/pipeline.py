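"""End-to-end orchestration: inclusion filter, fits, contrasts, artifacts.

A single :class:`AnalysisConfig` (optionally loaded from YAML) drives the
whole analysis — main run, the two sensitivity variants (ICU outcomes
without imputation; static lag-lead window) and the subgroup refits (BMI >
30; calorie-intake strata). :func:`run` returns a result bundle and, when
an output directory is given, writes every artifact (models as JSON, HR and
CIF curves as tidy CSV, a JSON-lines log) stamped with a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import effects, pamfit, ped
from .cohort import PatientRecord, read_cohort, write_cohort
from .exceptions import ConfigError
from .simulate import SimulationConfig, simulate_cohort

SUBGROUPS = ("all", "bmi_gt_30", "calorie_low", "calorie_moderate", "calorie_high")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    #: CSV inputs; leave None to simulate a synthetic cohort instead.
    admissions_csv: str | None = None
    patient_days_csv: str | None = None
    n_patients: int = 500  # synthetic cohort size when no CSVs are given
    seed: int = 0
    outcome_set: str = "hospital"  # or "icu" (sensitivity: no imputation)
    window_mode: str = "dynamic"  # or "static" (sensitivity: lag 4 / lead 60)
    basis_mode: str = "phase"  # or "surface"
    subgroup: str = "all"
    #: "reml", or a {penalty group: lambda} mapping; fixed values keep runs
    #: bit-for-bit reproducible.
    smoothing: str | dict = field(default_factory=lambda: {"default": 1.0, "re(icu_id)": 16.0})
    grid_cuts: list | None = None  # default: daily from 4 to 60
    output_dir: str | None = None

    def validate(self) -> None:
        if self.outcome_set not in ("hospital", "icu"):
            raise ConfigError("outcome_set must be 'hospital' or 'icu'")
        if self.window_mode not in ("dynamic", "static"):
            raise ConfigError("window_mode must be 'dynamic' or 'static'")
        if self.basis_mode not in ("phase", "surface"):
            raise ConfigError("basis_mode must be 'phase' or 'surface'")
        if self.subgroup not in SUBGROUPS:
            raise ConfigError(f"subgroup must be one of {SUBGROUPS}")
        if (self.admissions_csv is None) != (self.patient_days_csv is None):
            raise ConfigError("provide both CSV paths or neither")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def apply_inclusion(patients: list[PatientRecord]) -> tuple[list[PatientRecord], dict]:
    """Inclusion filter in flow-chart order, with an exclusion tally.

    Criteria: age >= 18 years; BMI > 13 kg/m2; at least 96 h (4 days) of
    ICU treatment; and at least one day with both medical nutrition therapy
    and mechanical ventilation during the first 96 h.
    """
    kept: list[PatientRecord] = []
    tally = {"age": 0, "bmi": 0, "icu_96h": 0, "mnt_mv": 0}
    for p in patients:
        if p.age < 18:
            tally["age"] += 1
            continue
        if p.bmi <= 13:
            tally["bmi"] += 1
            continue
        icu_los = p.icu_discharge_day if p.icu_discharge_day is not None else p.outcome_time
        if min(icu_los, p.outcome_time) < 4:
            tally["icu_96h"] += 1
            continue
        early_mnt = any(
            d.day_index <= 4 and not d.oral_only and (d.en_protein > 0 or d.pn_amino_acids > 0)
            for d in p.intake_days
        )
        if not (early_mnt and p.days_mv >= 1):
            tally["mnt_mv"] += 1
            continue
        kept.append(p)
    return kept, tally


def _apply_subgroup(patients: list[PatientRecord], subgroup: str) -> list[PatientRecord]:
    if subgroup == "all":
        return patients
    if subgroup == "bmi_gt_30":
        return [p for p in patients if p.bmi > 30]
    lo, hi = {"calorie_low": (0.0, 0.3), "calorie_moderate": (0.3, 0.7),
              "calorie_high": (0.7, float("inf"))}[subgroup]
    out = []
    for p in patients:
        if p.calorie_fraction is None:
            raise ConfigError(
                f"patient {p.patient_id} lacks the calorie_fraction column needed "
                f"for subgroup {subgroup!r}"
            )
        if lo <= p.calorie_fraction < hi:
            out.append(p)
    return out


def default_model_spec(cause: str, config: AnalysisConfig) -> pamfit.ModelSpec:
    """The confounder model used by the pipeline: P-spline baseline and
    smooth APACHE II / age / BMI effects, categorical sex / admission
    category / diagnosis / year, linear first-3-day therapy-day counts, an
    ICU random intercept, and the cumulative protein terms."""
    return pamfit.ModelSpec(
        cause=cause,
        baseline_type="ps",
        baseline_k=10,
        smooth=[
            pamfit.SmoothTerm("apache2", k=8),
            pamfit.SmoothTerm("age", k=8),
            pamfit.SmoothTerm("bmi", k=8),
        ],
        linear=["days_mv", "days_pn", "days_oral", "days_propofol"],
        categorical={
            "sex": "female",
            "admission_category": "medical",
            "diagnosis": "dx1",
            "year": "2007",
        },
        random_intercept="icu_id",
        cumulative=pamfit.CumulativeSpec(mode=config.basis_mode, basis="ps", k=5),
        smoothing=config.smoothing,
    )


@dataclass
class ResultBundle:
    config: AnalysisConfig
    n_included: int
    exclusion_tally: dict
    models: dict  # cause -> FittedHazardModel
    hr_curves: dict  # (cause, "diet_vs_reference") -> DataFrame
    cif_curves: dict  # diet name -> DataFrame
    log: list


def run(config: AnalysisConfig, patients: list[PatientRecord] | None = None) -> ResultBundle:
    """Execute the full analysis described by *config*.

    Deterministic given the seed (bit-for-bit with fixed smoothing
    parameters). Raises :class:`ConfigError` on an empty post-filter cohort
    before writing any output.
    """
    config.validate()
    log: list[dict] = []

    def note(event, **kw):
        log.append({"ts": time.time(), "event": event, **kw})

    note("config", **config.to_dict(), config_hash=config.config_hash())

    if patients is None:
        if config.admissions_csv is not None:
            patients = read_cohort(config.admissions_csv, config.patient_days_csv)
            note("loaded", n=len(patients))
        else:
            sim = SimulationConfig(
                n_patients=config.n_patients,
                rng_seed=config.seed,
                window_mode=config.window_mode,
            )
            patients = simulate_cohort(sim)
            note("simulated", n=len(patients))

    patients, tally = apply_inclusion(patients)
    note("inclusion", kept=len(patients), excluded=tally)
    patients = _apply_subgroup(patients, config.subgroup)
    note("subgroup", name=config.subgroup, kept=len(patients))
    if not patients:
        raise ConfigError("no patients remain after inclusion/subgroup filtering")

    grid = ped.IntervalGrid(np.asarray(config.grid_cuts, dtype=float)) if config.grid_cuts else ped.IntervalGrid()
    ped_df = ped.cohort_to_ped(
        patients, grid, cause_set=config.outcome_set, window_mode=config.window_mode
    )
    note("ped", rows=len(ped_df), events_death=int(ped_df["d_death"].sum()),
         events_discharge=int(ped_df["d_discharge"].sum()))

    models = {}
    for cause in ("death", "discharge"):
        spec = default_model_spec(cause, config)
        models[cause] = pamfit.fit(ped_df, spec)
        note("fit", cause=cause, edf=models[cause].edf, loglik=models[cause].loglik,
             lam={k: float(v) for k, v in models[cause].lam.items()})

    hr_curves = {}
    for ref, diet in effects.make_comparisons():
        for cause in ("death", "discharge"):
            key = (cause, f"{diet.name}_vs_{ref.name}")
            hr_curves[key] = effects.hr_curve(models[cause], diet, ref, config.window_mode)
    cif_curves = {}
    for name, diet in make_concrete_diets().items():
        cif_curves[name] = effects.cif(
            models["death"], models["discharge"], diet, window_mode=config.window_mode
        )
    note("curves", hr=len(hr_curves), cif=len(cif_curves))

    bundle = ResultBundle(
        config=config,
        n_included=len(patients),
        exclusion_tally=tally,
        models=models,
        hr_curves=hr_curves,
        cif_curves=cif_curves,
        log=log,
    )
    if config.output_dir:
        _write_bundle(bundle)
    return bundle


def make_concrete_diets() -> dict:
    """The five diets with unspecified days resolved in the standard
    (level II) context, for absolute-risk summaries."""
    diets = effects.make_diets()
    std = diets["early_standard"]
    return {name: d.resolved_against(std) for name, d in diets.items()}


def _write_bundle(bundle: ResultBundle) -> None:
    outdir = Path(bundle.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle.config.config_hash()
    stem = f"{bundle.config.outcome_set}_{bundle.config.window_mode}_{bundle.config.subgroup}"
    for cause, model in bundle.models.items():
        model.save(outdir / f"model_{stem}_{cause}_{h}.json")
    for (cause, pair), curve in bundle.hr_curves.items():
        effects.export_curve(curve, outdir / f"hr_{stem}_{cause}_{pair}_{h}.csv")
    for name, curve in bundle.cif_curves.items():
        effects.export_curve(curve, outdir / f"cif_{stem}_{name}_{h}.csv")
    with open(outdir / f"log_{stem}_{h}.jsonl", "w") as fh:
        for entry in bundle.log:
            fh.write(json.dumps(entry) + "\n")


__all__ = [
    "AnalysisConfig",
    "ResultBundle",
    "apply_inclusion",
    "default_model_spec",
    "make_concrete_diets",
    "run",
    "write_cohort",
]
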