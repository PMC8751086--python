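"""Hypothetical protein diets, hazard-ratio curves and absolute risks.

Five artificial 11-day diets (level trajectories) are contrasted pairwise
under the ceteris paribus assumption: two predictions that differ only in
the diet trajectory give a linear-predictor difference driven entirely by
the cumulative protein terms, so confounders and the ICU intercept cancel.
Hazard ratios are exp of that difference with delta-method 95% confidence
intervals; absolute risks are cumulative incidence functions combining both
cause-specific models.

Diet definitions follow the published table; on days a diet leaves
unspecified its intake is copied from the comparison diet, so the early
high diet is resolved per comparison (III on days #1-#4, the partner's
levels afterwards). Every comparison is oriented so the reference provides
component-wise fewer protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pamfit import FittedHazardModel
from .ped import (
    EARLY_DAYS,
    IntervalGrid,
    LagLeadWindow,
    N_DIET_DAYS,
    build_cumulative_design,
    level_dummies,
    window_for_diet,
)

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class HypotheticalDiet:
    """An 11-day intake-level trajectory; ``None`` marks unspecified days
    (resolved against the comparison diet)."""

    name: str
    levels: tuple

    def resolved_against(self, other: "HypotheticalDiet") -> "HypotheticalDiet":
        if all(l is not None for l in self.levels):
            return self
        filled = tuple(
            l if l is not None else o for l, o in zip(self.levels, other.levels)
        )
        if any(l is None for l in filled):
            raise ValueError("cannot resolve: comparison diet is itself unspecified")
        return HypotheticalDiet(self.name, filled)


def make_diets() -> dict[str, HypotheticalDiet]:
    """The five hypothetical protein diets.

    exclusively_low  I on all 11 days (about 0.49 g/kg per day)
    late_standard    I on #1-#4, II on #5-#11
    early_standard   II on all 11 days
    late_high        III on #5-#11 (days #1-#4 copied from the comparison)
    early_high       III on #1-#4 (days #5-#11 copied from the comparison)
    """
    return {
        "exclusively_low": HypotheticalDiet("exclusively_low", ("I",) * N_DIET_DAYS),
        "late_standard": HypotheticalDiet("late_standard", ("I",) * EARLY_DAYS + ("II",) * 7),
        "early_standard": HypotheticalDiet("early_standard", ("II",) * N_DIET_DAYS),
        "late_high": HypotheticalDiet("late_high", (None,) * EARLY_DAYS + ("III",) * 7),
        "early_high": HypotheticalDiet("early_high", ("III",) * EARLY_DAYS + (None,) * 7),
    }


_LEVEL_ORD = {"I": 0, "II": 1, "III": 2}


def make_comparisons() -> list[tuple[HypotheticalDiet, HypotheticalDiet]]:
    """The six pairwise diet comparisons as (reference, comparison) tuples.

    The reference always provides component-wise fewer (or equal) protein.
    Unspecified days are resolved within each pair: in the standard-vs-high
    family the standard (level II) context fills late_high's early days and
    early_high's late days; against late_high the early high diet continues
    at level III.
    """
    d = make_diets()
    std = d["early_standard"]  # the "standard protein diet" context, II all days
    late_high = d["late_high"].resolved_against(std)
    early_high_vs_std = d["early_high"].resolved_against(std)
    early_high_vs_late = d["early_high"].resolved_against(late_high)
    pairs = [
        (d["exclusively_low"], d["late_standard"]),
        (d["late_standard"], d["early_standard"]),
        (d["exclusively_low"], d["early_standard"]),
        (std, late_high),
        (late_high, early_high_vs_late),
        (std, early_high_vs_std),
    ]
    for ref, diet in pairs:
        if any(_LEVEL_ORD[a] > _LEVEL_ORD[b] for a, b in zip(ref.levels, diet.levels)):
            raise AssertionError("reference diet must provide fewer protein")
    return pairs


def _diet_frame(diet: HypotheticalDiet, grid: IntervalGrid, window_mode: str) -> pd.DataFrame:
    """Per-interval design inputs (window-weighted level indicators and
    phase counts) for a fully specified diet under the full-MNT window."""
    levels = list(diet.levels)
    if any(l is None for l in levels):
        raise ValueError(f"diet {diet.name!r} must be resolved before evaluation")
    window = window_for_diet(grid, window_mode)
    d2, d3 = level_dummies(levels)
    df = pd.DataFrame(
        {
            "interval": np.arange(grid.n_intervals),
            "t_start": grid.t_start,
            "t_end": grid.t_end,
            "t_mid": grid.t_mid,
        }
    )
    for j in range(N_DIET_DAYS):
        df[f"wII_{j + 1}"] = window.W[:, j] * d2[j]
        df[f"wIII_{j + 1}"] = window.W[:, j] * d3[j]
    for name, vals in build_cumulative_design(window, levels, "phase").items():
        df[name] = vals
    return df


def hr_curve(
    model: FittedHazardModel,
    diet: HypotheticalDiet,
    reference: HypotheticalDiet,
    window_mode: str | None = None,
) -> pd.DataFrame:
    """Time-varying cause-specific hazard ratio of *diet* vs *reference*.

    On intervals where the two diets are identical inside every
    contributing window the contrast vector is exactly zero, so the HR is
    exactly 1 with a degenerate [1, 1] confidence interval — in particular
    on the first interval (4, 5], where the 4-day lag excludes all diet
    days.
    """
    mode = window_mode or model.window_mode
    grid = IntervalGrid(model.grid_cuts)
    diet = diet.resolved_against(reference)
    reference = reference.resolved_against(diet)
    if len(diet.levels) != N_DIET_DAYS or len(reference.levels) != N_DIET_DAYS:
        raise ValueError("diets must cover days #1..#11")
    df_a = _diet_frame(diet, grid, mode)
    df_b = _diet_frame(reference, grid, mode)
    delta, se = model.cumulative_delta(df_a, df_b)
    out = pd.DataFrame(
        {
            "t_start": grid.t_start,
            "t_end": grid.t_end,
            "hr": np.exp(delta),
            "ci_low": np.exp(delta - Z95 * se),
            "ci_high": np.exp(delta + Z95 * se),
        }
    )
    out.attrs.update(
        cause=model.spec.cause, diet=diet.name, reference=reference.name, window_mode=mode
    )
    return out


def cif_from_hazards(
    h_death: np.ndarray, h_discharge: np.ndarray, widths: np.ndarray
) -> pd.DataFrame:
    """Cumulative incidence per cause and overall survival from piece-wise
    constant cause-specific hazards.

    With total hazard h = h_d + h_l on interval i of width w_i:
    S(j) = exp(-sum_{i<=j} h(i) w_i) and
    CIF_k(j) = sum_{i<=j} S(i-1) * (h_k(i)/h(i)) * (1 - exp(-h(i) w_i)),
    the proportional within-interval cause allocation that is exact for
    constant hazards. CIF_death + CIF_discharge + S = 1 identically.
    """
    h_death = np.asarray(h_death, dtype=float)
    h_discharge = np.asarray(h_discharge, dtype=float)
    widths = np.asarray(widths, dtype=float)
    tot = h_death + h_discharge
    inc_total = -np.expm1(-tot * widths)  # P(event in interval | at risk)
    S_prev = np.concatenate([[1.0], np.exp(-np.cumsum(tot * widths))])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_d = np.where(tot > 0, h_death / np.where(tot > 0, tot, 1.0), 0.0)
    inc_d = S_prev[:-1] * frac_d * inc_total
    inc_l = S_prev[:-1] * (np.where(tot > 0, 1.0, 0.0) - frac_d) * inc_total
    return pd.DataFrame(
        {
            "cif_death": np.cumsum(inc_d),
            "cif_discharge": np.cumsum(inc_l),
            "surv": S_prev[1:],
        }
    )


def cif(
    model_death: FittedHazardModel,
    model_discharge: FittedHazardModel,
    diet: HypotheticalDiet,
    profile: dict | None = None,
    window_mode: str | None = None,
) -> pd.DataFrame:
    """Absolute risks under a hypothetical diet for a covariate profile.

    Both cause-specific models must share one interval grid. The default
    profile is population-average: ICU intercept zero, categorical
    confounders at their reference, continuous confounders at the training
    median. ``profile`` entries override individual covariates.
    """
    if not np.array_equal(model_death.grid_cuts, model_discharge.grid_cuts):
        raise ValueError("cause-specific models use different interval grids")
    mode = window_mode or model_death.window_mode
    grid = IntervalGrid(model_death.grid_cuts)
    if any(l is None for l in diet.levels):
        raise ValueError(f"diet {diet.name!r} must be resolved before evaluation")
    df = _diet_frame(diet, grid, mode)
    for col, val in (profile or {}).items():
        df[col] = val
    eta_d, _ = model_death.predict_log_hazard(df, population=True)
    eta_l, _ = model_discharge.predict_log_hazard(df, population=True)
    widths = grid.t_end - grid.t_start
    out = cif_from_hazards(np.exp(eta_d), np.exp(eta_l), widths)
    out.insert(0, "t_end", grid.t_end)
    out.insert(0, "t_start", grid.t_start)
    out.attrs.update(diet=diet.name, window_mode=mode)
    return out


def export_curve(curve: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy per-interval curve (HR or CIF) to CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_csv(path, index=False)
    return path


def plot_hr(curve: pd.DataFrame, ax=None):
    """Step plot of an HR curve with its 95% CI ribbon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    t = curve["t_start"].to_numpy()
    ax.step(t, curve["hr"], where="post", color="C0")
    ax.fill_between(t, curve["ci_low"], curve["ci_high"], step="post", alpha=0.25, color="C0")
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    ax.set_yscale("log")
    ax.set_xlabel("days after ICU admission")
    ax.set_ylabel("hazard ratio")
    if "diet" in curve.attrs:
        ax.set_title(
            f"{curve.attrs['diet']} vs {curve.attrs['reference']} ({curve.attrs['cause']})",
            fontsize=9,
        )
    return ax


def plot_cif(curve: pd.DataFrame, ax=None):
    """Stacked view of CIF_death, CIF_discharge and survival."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    t = curve["t_end"].to_numpy()
    ax.plot(t, curve["cif_death"], label="in-hospital death", color="C3")
    ax.plot(t, curve["cif_discharge"], label="live discharge", color="C2")
    ax.plot(t, curve["surv"], label="still in hospital", color="C7")
    ax.set_xlabel("days after ICU admission")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
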