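"""Penalized Poisson fitting of cause-specific piece-wise exponential models.

Each competing cause (in-hospital death, live hospital discharge) is fitted
separately on the same PED rows, with the other cause's events acting as
censoring — the standard cause-specific hazard construction. The model is

    log lambda(t, x) = f0(t) + sum_j f_j(x_j) + gamma' x_lin + b_ICU
                       + cumulative protein terms,

estimated by maximizing the penalized Poisson log-likelihood

    sum_i [ delta_i eta_i - exp(eta_i + offset_i) ] - 1/2 sum_m lam_m b' S_m b

via penalized IRLS. Smooth terms are P-splines (cubic B-splines with a
second-order difference penalty); the ICU random intercept is an identity-
penalized (ridge) block, exploiting the mixed-model-as-penalty equivalence
lam = 1/sigma^2; smoothing parameters are chosen by a Laplace-approximate
REML criterion (outer optimization on log lam) or fixed for exact
reproducibility. The reported covariance is the Bayesian posterior
covariance (X'WX + S_lam)^{-1} of the penalized fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import ConvergenceError
from .ped import N_DIET_DAYS, PHASE_COLUMNS
from .splines import (
    bspline_design,
    difference_penalty,
    row_kron,
    sum_to_zero_constraint,
    tensor_penalties,
)

_ETA_CAP = 30.0  # cap on eta + offset before exponentiation
_RIDGE = 1e-8  # numerical ridge on the penalized Hessian


@dataclass
class SmoothTerm:
    """P-spline smooth of one continuous confounder."""

    col: str
    k: int = 8
    degree: int = 3
    penalty_order: int = 2


@dataclass
class CumulativeSpec:
    """How the cumulative protein terms enter the linear predictor.

    ``phase`` mode uses the four early/late x level-II/III weighted counts,
    each multiplied by a coefficient function of follow-up time (P-spline of
    size ``k``, or a constant when ``basis == "constant"``). ``surface``
    mode uses a tensor-product P-spline surface g(t, t_z) per level dummy,
    contracted against the window indicators.
    """

    mode: str = "phase"
    basis: str = "ps"
    k: int = 5
    k_t: int = 5
    k_z: int = 5
    degree: int = 3
    penalty_order: int = 2


@dataclass
class ModelSpec:
    """Specification of one cause-specific hazard model."""

    cause: str = "death"
    baseline_type: str = "ps"  # "ps" smooth log-baseline or "pwc" per-interval
    baseline_k: int = 10
    smooth: list[SmoothTerm] = field(default_factory=list)
    linear: list[str] = field(default_factory=list)
    categorical: dict[str, str] = field(default_factory=dict)  # col -> reference
    random_intercept: str | None = None
    cumulative: CumulativeSpec | None = field(default_factory=CumulativeSpec)
    #: "reml", or a mapping {penalty group -> lambda} (key "default" filled in
    #: for unlisted groups) for fixed smoothing parameters.
    smoothing: str | dict = "reml"

    def __post_init__(self):
        if self.cause not in ("death", "discharge"):
            raise ValueError("cause must be 'death' or 'discharge'")


# --------------------------------------------------------------------------
# design construction


class DesignBuilder:
    """Builds the model matrix from a PED frame and replays it on new data.

    Blocks are built in a fixed order (intercept, baseline, smooths, linear,
    categorical, random intercept, cumulative). All state needed to rebuild
    a design row — knot ranges, constraint transforms, category levels,
    training medians — is stored as plain arrays/lists so fitted models
    serialize to JSON.
    """

    def __init__(self, spec: ModelSpec, grid_cuts: np.ndarray):
        self.spec = spec
        self.grid_cuts = np.asarray(grid_cuts, dtype=float)
        self.blocks: list[dict] = []

    # -- fitting-side construction

    def fit(self, ped: pd.DataFrame) -> np.ndarray:
        spec = self.spec
        self.blocks = []
        tmin, tmax = float(self.grid_cuts[0]), float(self.grid_cuts[-1])
        if spec.baseline_type == "pwc":
            self.blocks.append(
                {"name": "baseline", "kind": "pwc", "n_intervals": len(self.grid_cuts) - 1}
            )
        elif spec.baseline_type == "ps":
            self.blocks.append({"name": "intercept", "kind": "intercept"})
            B = bspline_design(ped["t_mid"].to_numpy(), tmin, tmax, spec.baseline_k)
            Z = sum_to_zero_constraint(B)
            self.blocks.append(
                {
                    "name": "baseline",
                    "kind": "ps",
                    "col": "t_mid",
                    "xmin": tmin,
                    "xmax": tmax,
                    "k": spec.baseline_k,
                    "degree": 3,
                    "penalty_order": 2,
                    "Z": Z,
                    "default": float(np.median(ped["t_mid"])),
                    "lam_group": "baseline",
                }
            )
        else:
            raise ValueError(f"unknown baseline type {self.spec.baseline_type!r}")
        for term in spec.smooth:
            x = ped[term.col].to_numpy(dtype=float)
            xmin, xmax = float(x.min()), float(x.max())
            if xmax <= xmin:
                raise ValueError(f"smooth covariate {term.col!r} is constant")
            B = bspline_design(x, xmin, xmax, term.k, term.degree)
            Z = sum_to_zero_constraint(B)
            self.blocks.append(
                {
                    "name": f"s({term.col})",
                    "kind": "ps",
                    "col": term.col,
                    "xmin": xmin,
                    "xmax": xmax,
                    "k": term.k,
                    "degree": term.degree,
                    "penalty_order": term.penalty_order,
                    "Z": Z,
                    "default": float(np.median(x)),
                    "lam_group": f"s({term.col})",
                }
            )
        for col in spec.linear:
            self.blocks.append(
                {
                    "name": col,
                    "kind": "linear",
                    "col": col,
                    "center": float(np.mean(ped[col].to_numpy(dtype=float))),
                }
            )
        for col, ref in spec.categorical.items():
            levels = sorted(str(v) for v in pd.unique(ped[col].astype(str)))
            if str(ref) not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            self.blocks.append(
                {
                    "name": col,
                    "kind": "categorical",
                    "col": col,
                    "reference": str(ref),
                    "levels": [l for l in levels if l != str(ref)],
                }
            )
        if spec.random_intercept is not None:
            col = spec.random_intercept
            levels = sorted(str(v) for v in pd.unique(ped[col].astype(str)))
            self.blocks.append(
                {
                    "name": f"re({col})",
                    "kind": "random",
                    "col": col,
                    "levels": levels,
                    "lam_group": f"re({col})",
                }
            )
        if spec.cumulative is not None:
            cum = spec.cumulative
            if cum.mode == "phase":
                self.blocks.append(
                    {
                        "name": "cumulative",
                        "kind": "cum_phase",
                        "basis": cum.basis,
                        "k": cum.k,
                        "degree": cum.degree,
                        "penalty_order": cum.penalty_order,
                        "xmin": tmin,
                        "xmax": tmax,
                        "lam_group": None if cum.basis == "constant" else "cumulative",
                    }
                )
            elif cum.mode == "surface":
                self.blocks.append(
                    {
                        "name": "cumulative",
                        "kind": "cum_surface",
                        "k_t": cum.k_t,
                        "k_z": cum.k_z,
                        "degree": cum.degree,
                        "penalty_order": cum.penalty_order,
                        "xmin": tmin,
                        "xmax": tmax,
                    }
                )
            else:
                raise ValueError(f"unknown cumulative mode {cum.mode!r}")
        return self.transform(ped)

    # -- shared design evaluation

    def _block_design(self, blk: dict, df: pd.DataFrame, population: bool) -> np.ndarray:
        n = len(df)
        kind = blk["kind"]
        if kind == "intercept":
            return np.ones((n, 1))
        if kind == "pwc":
            X = np.zeros((n, blk["n_intervals"]))
            X[np.arange(n), df["interval"].to_numpy(dtype=int)] = 1.0
            return X
        if kind == "ps":
            if blk["col"] in df.columns:
                x = df[blk["col"]].to_numpy(dtype=float)
            else:
                x = np.full(n, blk["default"])
            B = bspline_design(x, blk["xmin"], blk["xmax"], blk["k"], blk["degree"])
            return B @ blk["Z"]
        if kind == "linear":
            if blk["col"] in df.columns:
                x = df[blk["col"]].to_numpy(dtype=float)
            else:
                x = np.full(n, blk["center"])
            return (x - blk["center"])[:, None]
        if kind == "categorical":
            X = np.zeros((n, len(blk["levels"])))
            if blk["col"] in df.columns:
                vals = df[blk["col"]].astype(str).to_numpy()
                known = set(blk["levels"]) | {blk["reference"]}
                unseen = sorted(set(vals) - known)
                if unseen:
                    raise ValueError(f"unseen level(s) {unseen} for {blk['col']!r}")
                for j, lev in enumerate(blk["levels"]):
                    X[:, j] = vals == lev
            return X
        if kind == "random":
            X = np.zeros((n, len(blk["levels"])))
            if population or blk["col"] not in df.columns:
                return X
            vals = df[blk["col"]].astype(str).to_numpy()
            index = {lev: j for j, lev in enumerate(blk["levels"])}
            for i, v in enumerate(vals):
                j = index.get(v)
                if j is not None:
                    X[i, j] = 1.0
            return X
        if kind == "cum_phase":
            counts = np.column_stack([df[c].to_numpy(dtype=float) for c in PHASE_COLUMNS])
            if blk["basis"] == "constant":
                return counts
            B = bspline_design(
                df["t_mid"].to_numpy(dtype=float), blk["xmin"], blk["xmax"], blk["k"], blk["degree"]
            )
            return np.column_stack([B * counts[:, j : j + 1] for j in range(4)]).reshape(
                len(df), -1
            )
        if kind == "cum_surface":
            Bt = bspline_design(
                df["t_mid"].to_numpy(dtype=float), blk["xmin"], blk["xmax"], blk["k_t"], blk["degree"]
            )
            Bz = bspline_design(
                np.arange(1.0, N_DIET_DAYS + 1), 1.0, float(N_DIET_DAYS), blk["k_z"], blk["degree"]
            )
            parts = []
            for dummy in ("II", "III"):
                M = np.column_stack(
                    [df[f"w{dummy}_{j + 1}"].to_numpy(dtype=float) for j in range(N_DIET_DAYS)]
                )
                parts.append(row_kron(Bt, M @ Bz))
            return np.hstack(parts)
        raise ValueError(f"unknown block kind {kind!r}")

    def block_ncols(self, blk: dict) -> int:
        kind = blk["kind"]
        if kind == "intercept":
            return 1
        if kind == "pwc":
            return blk["n_intervals"]
        if kind == "ps":
            return blk["k"] - 1
        if kind == "linear":
            return 1
        if kind == "categorical":
            return len(blk["levels"])
        if kind == "random":
            return len(blk["levels"])
        if kind == "cum_phase":
            return 4 if blk["basis"] == "constant" else 4 * blk["k"]
        if kind == "cum_surface":
            return 2 * blk["k_t"] * blk["k_z"]
        raise ValueError(kind)

    def transform(self, df: pd.DataFrame, population: bool = False) -> np.ndarray:
        return np.hstack([self._block_design(b, df, population) for b in self.blocks])

    def block_slice(self, name: str) -> slice:
        start = 0
        for blk in self.blocks:
            ncol = self.block_ncols(blk)
            if blk["name"] == name:
                return slice(start, start + ncol)
            start += ncol
        raise KeyError(name)

    @property
    def n_cols(self) -> int:
        return sum(self.block_ncols(b) for b in self.blocks)

    def penalties(self) -> list[tuple[str, np.ndarray]]:
        """(group name, full-size penalty matrix) pairs, one per smoothing
        parameter; matrices are embedded at the block's column offset."""
        out = []
        p = self.n_cols
        start = 0
        for blk in self.blocks:
            ncol = self.block_ncols(blk)
            local: list[tuple[str, np.ndarray]] = []
            if blk["kind"] == "ps":
                S = blk["Z"].T @ difference_penalty(blk["k"], blk["penalty_order"]) @ blk["Z"]
                local.append((blk["lam_group"], S))
            elif blk["kind"] == "random":
                local.append((blk["lam_group"], np.eye(ncol)))
            elif blk["kind"] == "cum_phase" and blk["basis"] != "constant":
                Sk = difference_penalty(blk["k"], blk["penalty_order"])
                S = np.kron(np.eye(4), Sk)
                local.append((blk["lam_group"], S))
            elif blk["kind"] == "cum_surface":
                St, Sz = tensor_penalties(blk["k_t"], blk["k_z"], blk["penalty_order"])
                local.append(("cumulative_t", np.kron(np.eye(2), St)))
                local.append(("cumulative_z", np.kron(np.eye(2), Sz)))
            for group, S in local:
                full = np.zeros((p, p))
                full[start : start + ncol, start : start + ncol] = S
                out.append((group, full))
            start += ncol
        return out


# --------------------------------------------------------------------------
# fitting


def _poisson_ll(y, eta_off):
    """Unpenalized Poisson log-likelihood (event indicators, so log y! = 0)."""
    mu = np.exp(np.minimum(eta_off, _ETA_CAP))
    return float(y @ eta_off - mu.sum())


def _pirls(X, y, off, S, beta0=None, max_iter=200, tol=1e-10):
    """Penalized IRLS for the Poisson log link with offset.

    Returns (beta, penalized ll, trace). Steps are halved whenever the
    penalized log-likelihood would decrease.
    """
    n, p = X.shape
    if beta0 is None:
        z0 = np.log((y + 0.1) / np.exp(off))
        w0 = np.exp(off)
        H0 = X.T @ (X * w0[:, None]) + S + _RIDGE * np.eye(p)
        beta = np.linalg.solve(H0, X.T @ (w0 * z0))
    else:
        beta = beta0.copy()

    def pll(b):
        return _poisson_ll(y, X @ b + off) - 0.5 * b @ S @ b

    cur = pll(beta)
    trace = [cur]
    for _ in range(max_iter):
        eta_off = np.minimum(X @ beta + off, _ETA_CAP)
        mu = np.exp(eta_off)
        H = X.T @ (X * mu[:, None]) + S + _RIDGE * np.eye(p)
        score = X.T @ (y - mu) - S @ beta
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        new = pll(beta + step)
        halvings = 0
        while not np.isfinite(new) or new < cur - 1e-12:
            step *= 0.5
            new = pll(beta + step)
            halvings += 1
            if halvings > 40:
                break
        if halvings > 40 and (not np.isfinite(new) or new < cur):
            return beta, cur, trace  # no ascent direction left at fp precision
        beta = beta + step
        trace.append(new)
        if abs(new - cur) < tol * (abs(cur) + 1.0):
            return beta, new, trace
        cur = new
    if abs(trace[-1] - trace[-2]) > 1e-6 * (abs(trace[-2]) + 1.0):
        raise ConvergenceError(
            f"penalized IRLS did not converge in {max_iter} iterations", trace
        )
    return beta, cur, trace


def _logdet_psd(S, tol=1e-10):
    ev = np.linalg.eigvalsh(S)
    keep = ev > tol * max(ev.max(), 1.0)
    return float(np.sum(np.log(ev[keep]))), int(keep.sum())


@dataclass
class FittedHazardModel:
    """One fitted cause-specific hazard model.

    Carries the coefficient vector, the Bayesian covariance of the penalized
    fit, smoothing parameters, the interval grid, and the design builder
    needed to reproduce the linear predictor for new data or hypothetical
    diet profiles.
    """

    spec: ModelSpec
    builder: DesignBuilder
    grid_cuts: np.ndarray
    beta: np.ndarray
    Vbeta: np.ndarray
    lam: dict
    edf: float
    loglik: float
    iterations: int
    converged: bool
    window_mode: str = "dynamic"

    # -- prediction

    def linear_predictor(self, df: pd.DataFrame, population: bool = False) -> np.ndarray:
        return self.builder.transform(df, population=population) @ self.beta

    def predict_log_hazard(
        self, df: pd.DataFrame, population: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Linear predictor (log hazard) and its standard error.

        With ``population=True`` the ICU random intercept is set to its mean
        (zero), the convention for hypothetical-diet predictions.
        """
        X = self.builder.transform(df, population=population)
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.Vbeta, X), 0.0))
        return eta, se

    def cumulative_delta(
        self, df_a: pd.DataFrame, df_b: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray]:
        """Difference in the cumulative-term linear predictor between two
        diet profiles (all other covariates cancel), with its SE."""
        sl = self.builder.block_slice("cumulative")
        blk = next(b for b in self.builder.blocks if b["name"] == "cumulative")
        Xa = self.builder._block_design(blk, df_a, True)
        Xb = self.builder._block_design(blk, df_b, True)
        D = Xa - Xb
        delta = D @ self.beta[sl]
        V = self.Vbeta[sl, sl.start : sl.stop]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, V, D), 0.0))
        return delta, se

    # -- serialization

    def to_dict(self) -> dict:
        def enc(v):
            if isinstance(v, np.ndarray):
                return {"__array__": v.tolist()}
            return v

        return {
            "schema": "icupam-model/1",
            "spec": {
                "cause": self.spec.cause,
                "baseline_type": self.spec.baseline_type,
                "baseline_k": self.spec.baseline_k,
                "smooth": [vars(t) for t in self.spec.smooth],
                "linear": self.spec.linear,
                "categorical": self.spec.categorical,
                "random_intercept": self.spec.random_intercept,
                "cumulative": None if self.spec.cumulative is None else vars(self.spec.cumulative),
                "smoothing": self.spec.smoothing if isinstance(self.spec.smoothing, str) else dict(self.spec.smoothing),
            },
            "grid_cuts": self.grid_cuts.tolist(),
            "blocks": [{k: enc(v) for k, v in blk.items()} for blk in self.builder.blocks],
            "beta": self.beta.tolist(),
            "Vbeta": self.Vbeta.tolist(),
            "lam": self.lam,
            "edf": self.edf,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "window_mode": self.window_mode,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedHazardModel":
        sp = d["spec"]
        spec = ModelSpec(
            cause=sp["cause"],
            baseline_type=sp["baseline_type"],
            baseline_k=sp["baseline_k"],
            smooth=[SmoothTerm(**t) for t in sp["smooth"]],
            linear=list(sp["linear"]),
            categorical=dict(sp["categorical"]),
            random_intercept=sp["random_intercept"],
            cumulative=None if sp["cumulative"] is None else CumulativeSpec(**sp["cumulative"]),
            smoothing=sp["smoothing"],
        )
        grid_cuts = np.asarray(d["grid_cuts"], dtype=float)
        builder = DesignBuilder(spec, grid_cuts)

        def dec(v):
            if isinstance(v, dict) and "__array__" in v:
                return np.asarray(v["__array__"], dtype=float)
            return v

        builder.blocks = [{k: dec(v) for k, v in blk.items()} for blk in d["blocks"]]
        return cls(
            spec=spec,
            builder=builder,
            grid_cuts=grid_cuts,
            beta=np.asarray(d["beta"], dtype=float),
            Vbeta=np.asarray(d["Vbeta"], dtype=float),
            lam=dict(d["lam"]),
            edf=float(d["edf"]),
            loglik=float(d["loglik"]),
            iterations=int(d["iterations"]),
            converged=bool(d["converged"]),
            window_mode=d.get("window_mode", "dynamic"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedHazardModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(ped: pd.DataFrame, spec: ModelSpec) -> FittedHazardModel:
    """Fit one cause-specific penalized Poisson hazard model on PED rows."""
    grid_cuts = np.asarray(
        ped.attrs.get("grid_cuts", np.arange(4.0, 61.0)), dtype=float
    )
    builder = DesignBuilder(spec, grid_cuts)
    X = builder.fit(ped)
    y = ped[f"d_{spec.cause}"].to_numpy(dtype=float)
    off = ped["offset"].to_numpy(dtype=float)

    # zero columns carry no information (unobserved category / empty window
    # day): drop from the fit, restore zero coefficients afterwards.
    nonzero = np.flatnonzero(np.any(X != 0.0, axis=0))
    dropped = X.shape[1] - len(nonzero)
    if dropped:
        warnings.warn(f"dropping {dropped} all-zero design column(s)", stacklevel=2)
    Xf = X[:, nonzero]

    penalties = [(g, S[np.ix_(nonzero, nonzero)]) for g, S in builder.penalties()]
    groups = sorted({g for g, _ in penalties})

    def assemble(lam: dict) -> np.ndarray:
        S = np.zeros((Xf.shape[1], Xf.shape[1]))
        for g, Sg in penalties:
            S += lam[g] * Sg
        return S

    if isinstance(spec.smoothing, dict):
        lam = {g: float(spec.smoothing.get(g, spec.smoothing.get("default", 1.0))) for g in groups}
        beta_f, pll, trace = _pirls(Xf, y, off, assemble(lam))
    elif spec.smoothing == "reml":
        warm = {"beta": None}

        def neg_reml(loglam_vec):
            lam_try = {g: float(np.exp(np.clip(v, -16, 16))) for g, v in zip(groups, loglam_vec)}
            S = assemble(lam_try)
            try:
                b, _, _ = _pirls(Xf, y, off, S, beta0=warm["beta"])
            except ConvergenceError:
                return 1e10
            warm["beta"] = b
            eta_off = np.minimum(Xf @ b + off, _ETA_CAP)
            mu = np.exp(eta_off)
            ll = _poisson_ll(y, eta_off)
            H = Xf.T @ (Xf * mu[:, None]) + S + _RIDGE * np.eye(Xf.shape[1])
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            logdetS, _ = _logdet_psd(S) if groups else (0.0, 0)
            return -(ll - 0.5 * b @ S @ b + 0.5 * logdetS - 0.5 * logdetH)

        if groups:
            x0 = np.zeros(len(groups))
            res = minimize(
                neg_reml, x0, method="Nelder-Mead",
                options={"maxiter": 80 * max(len(groups), 1), "fatol": 1e-4, "xatol": 1e-2},
            )
            lam = {g: float(np.exp(np.clip(v, -16, 16))) for g, v in zip(groups, res.x)}
        else:
            lam = {}
        beta_f, pll, trace = _pirls(Xf, y, off, assemble(lam))
    else:
        raise ValueError("smoothing must be 'reml' or a {group: lambda} mapping")

    S = assemble(lam)
    eta_off = np.minimum(Xf @ beta_f + off, _ETA_CAP)
    mu = np.exp(eta_off)
    H = Xf.T @ (Xf * mu[:, None]) + S + _RIDGE * np.eye(Xf.shape[1])
    Hinv = np.linalg.inv(H)
    edf = float(np.trace(Hinv @ (Xf.T @ (Xf * mu[:, None]))))

    p = X.shape[1]
    beta = np.zeros(p)
    beta[nonzero] = beta_f
    Vbeta = np.zeros((p, p))
    Vbeta[np.ix_(nonzero, nonzero)] = 0.5 * (Hinv + Hinv.T)

    return FittedHazardModel(
        spec=spec,
        builder=builder,
        grid_cuts=grid_cuts,
        beta=beta,
        Vbeta=Vbeta,
        lam=lam,
        edf=edf,
        loglik=_poisson_ll(y, eta_off),
        iterations=len(trace) - 1,
        converged=True,
        window_mode=str(ped.attrs.get("window_mode", "dynamic")),
    )


def loglik(model: FittedHazardModel, ped: pd.DataFrame) -> float:
    """Unpenalized Poisson log-likelihood of *model* on PED rows.

    Up to an additive constant (the sum of log final-interval exposures over
    events) this equals the piece-wise exponential survival log-likelihood
    sum_i [delta_i log lambda(t_i) - Lambda(t_i)].
    """
    X = model.builder.transform(ped)
    y = ped[f"d_{model.spec.cause}"].to_numpy(dtype=float)
    eta_off = X @ model.beta + ped["offset"].to_numpy(dtype=float)
    return _poisson_ll(y, eta_off)
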