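"""Fitting the heterogeneity parameters to clonogenic survival data.

A clonogenic experiment measures surviving fractions at graded single doses
for a parental line ("pre" arm) and, optionally, for a line re-grown after a
stated conditioning course ("post" arm).  Under the heterogeneity model both
arms are predicted from one parameter set: the post arm's composition is the
pre-treatment distribution re-weighted by per-fraction LQ survival over the
conditioning course (repopulation is excluded during fitting — a uniform
rate would cancel out of the surviving-fraction ratio anyway).

Fitting minimizes the sum of squared residuals in log surviving fraction
(clonogenic noise is multiplicative) over a user-chosen free subset of
{alpha_c, beta_c, sigma_alpha, sigma_beta}, with bounded derivative-free
local search from multiple jittered starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import FractionationSchedule
from .errors import FitError, GridConstructionError, InputDomainError
from .grid import (
    GaussianHeterogeneityParams,
    GridConfig,
    PopulationSummary,
    RadiosensitivityGrid,
    build_grid,
    population_survival,
    summarize,
)

__all__ = [
    "AssayMeasurementSet",
    "FitResult",
    "predict_assay",
    "evolve_composition",
    "fit_params",
    "tabulate_shift",
]

PARAM_NAMES = ("alpha_c", "beta_c", "sigma_alpha", "sigma_beta")

#: Optimizer box constraints, generous around the parameter scales seen in
#: published clonogenic fits.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_c": (0.01, 1.5),
    "beta_c": (0.002, 0.2),
    "sigma_alpha": (1e-3, 0.5),
    "sigma_beta": (1e-5, 0.05),
}


@dataclass(frozen=True)
class AssayMeasurementSet:
    """(dose, surviving fraction) observations for pre and/or post arms."""

    data: pd.DataFrame  # columns: dose_gy, surviving_fraction, arm, replicate
    course: FractionationSchedule | None = None

    def __post_init__(self) -> None:
        required = {"dose_gy", "surviving_fraction", "arm"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputDomainError(f"measurement table missing columns {sorted(missing)}")
        if len(self.data) == 0:
            raise InputDomainError("measurement table is empty")
        if (self.data["dose_gy"] <= 0).any():
            raise InputDomainError("assay doses must be > 0 Gy")
        sf = self.data["surviving_fraction"]
        if ((sf <= 0) | (sf > 1)).any():
            raise InputDomainError("surviving fractions must lie in (0, 1]")
        bad = set(self.data["arm"]) - {"pre", "post"}
        if bad:
            raise InputDomainError(f"arm must be 'pre' or 'post', got {sorted(bad)}")
        if "post" in set(self.data["arm"]) and self.course is None:
            raise InputDomainError("a post arm requires a conditioning course")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.data["arm"])))

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, course: FractionationSchedule | None = None
    ) -> "AssayMeasurementSet":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise InputDomainError(f"measurement CSV {path} is empty") from exc
        for i, row in df.iterrows():
            for col in ("dose_gy", "surviving_fraction"):
                if col not in df.columns:
                    raise InputDomainError(f"{path}: missing column {col!r}")
                try:
                    float(row[col])
                except (TypeError, ValueError) as exc:
                    raise InputDomainError(
                        f"{path}: row {i}, column {col!r}: not a number ({row[col]!r})"
                    ) from exc
        return cls(df, course=course)


def evolve_composition(
    grid: RadiosensitivityGrid, course: FractionationSchedule
) -> RadiosensitivityGrid:
    """Composition after a course of pure selection (no repopulation).

    Without repopulation, per-fraction re-weightings commute and compound
    into a single multiplier: the product of LQ survival over all events.
    """
    log_w = np.zeros(grid.shape)
    A, B = grid.alpha_mesh, grid.beta_mesh
    for _, dose in course.events:
        log_w -= dose * (A + B * dose)
    return grid.reweighted(np.where(grid.support, np.exp(log_w), 0.0))


def predict_assay(
    params: GaussianHeterogeneityParams,
    config: GridConfig = GridConfig(),
    course: FractionationSchedule | None = None,
    doses: Sequence[float] = (2.0, 4.0, 6.0),
) -> np.ndarray:
    """Model surviving fractions of a clonogenic assay at the given test doses.

    With ``course=None`` this is the pre-treatment population; otherwise the
    composition is first evolved through the conditioning course by pure
    selection.  Each prediction is the density-weighted population survival
    at a single test dose.
    """
    grid = build_grid(params, config)
    if course is not None:
        grid = evolve_composition(grid, course)
    return np.array([population_survival(grid, d, 1) for d in doses])


@dataclass(frozen=True)
class FitResult:
    params: GaussianHeterogeneityParams
    free_parameters: tuple[str, ...]
    fixed_parameters: Mapping[str, float]
    objective: float
    residuals: pd.DataFrame
    success: bool
    message: str
    n_evaluations: int
    summary_pre: PopulationSummary
    summary_post: PopulationSummary | None = None
    starts: tuple[dict, ...] = field(default=(), compare=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params.as_dict(),
            "free_parameters": list(self.free_parameters),
            "fixed_parameters": dict(self.fixed_parameters),
            "objective": self.objective,
            "success": self.success,
            "message": self.message,
            "n_evaluations": self.n_evaluations,
            "residuals": self.residuals.to_dict(orient="records"),
            "summary_pre": self.summary_pre.as_dict(),
            "summary_post": self.summary_post.as_dict() if self.summary_post else None,
            "starts": list(self.starts),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _objective_factory(data, config, free, fixed):
    # Pre-index the data once: per arm, unique test doses plus the inverse
    # map from each measurement row to its dose, so replicates share one
    # forward evaluation.
    rows = data.data
    arm_index = {}
    for arm in data.arms:
        d = rows.loc[rows["arm"] == arm, "dose_gy"].to_numpy()
        uniq, inv = np.unique(d, return_inverse=True)
        logsf = np.log(rows.loc[rows["arm"] == arm, "surviving_fraction"].to_numpy())
        arm_index[arm] = (uniq, inv, logsf)
    course_doses = (
        np.array([dose for _, dose in data.course.events]) if data.course else None
    )

    def objective(theta: np.ndarray) -> float:
        kwargs = dict(fixed)
        kwargs.update(dict(zip(free, theta)))
        try:
            params = GaussianHeterogeneityParams(**kwargs)
            grid = build_grid(params, config)
        except (InputDomainError, GridConstructionError):
            return 1e12  # out-of-domain trial point
        # flattened support arrays: one vectorized exp per arm
        sup = grid.support
        a = grid.alpha_mesh[sup]
        b = grid.beta_mesh[sup]
        w = grid.density[sup]
        total = 0.0
        for arm, (uniq, inv, logsf) in arm_index.items():
            wa = w
            if arm == "post":
                log_m = -(course_doses[:, None] * (a + b * course_doses[:, None])).sum(axis=0)
                wa = w * np.exp(log_m)
                wa = wa / wa.sum()
            sf = np.exp(-uniq[:, None] * (a + b * uniq[:, None]))  # (ndose, ncells)
            pred = sf @ wa
            total += float(((np.log(pred)[inv] - logsf) ** 2).sum())
        return total

    return objective


def fit_params(
    data: AssayMeasurementSet,
    config: GridConfig = GridConfig(),
    free_parameters: Sequence[str] = ("alpha_c",),
    initial_guess: GaussianHeterogeneityParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    xatol: float = 1e-5,
    fatol: float = 1e-6,
) -> FitResult:
    """Least-squares fit of the heterogeneity parameters in log surviving fraction.

    Parameters listed in ``free_parameters`` are optimized (Nelder-Mead with
    box bounds, ``n_starts`` multiplicatively jittered starts around the
    initial guess, seeded); the rest are held at the initial guess.

    Raises
    ------
    FitError
        If fewer measurements than free parameters (under-determined), or an
        unknown parameter name is requested.
    """
    free = tuple(free_parameters)
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise FitError(f"unknown free parameters: {sorted(unknown)}")
    if not free:
        raise FitError("at least one free parameter is required")
    if len(data) < len(free):
        raise FitError(
            f"under-determined fit: {len(data)} measurements for {len(free)} free parameters"
        )
    if initial_guess is None:
        raise FitError("an initial guess is required")
    fixed = {k: v for k, v in initial_guess.as_dict().items() if k not in free}
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    objective = _objective_factory(data, config, free, fixed)

    rng = np.random.default_rng(seed)
    x0 = np.array([getattr(initial_guess, k) for k in free])
    lo = np.array([bnds[k][0] for k in free])
    hi = np.array([bnds[k][1] for k in free])
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        jitter = np.exp(rng.normal(0.0, 0.15, size=len(free)))
        starts.append(np.clip(x0 * jitter, lo, hi))

    best = None
    trace = []
    n_evals = 0
    for s in starts:
        res = optimize.minimize(
            objective,
            s,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": xatol, "fatol": fatol, "maxiter": 200 * len(free)},
        )
        n_evals += res.nfev
        trace.append({"start": dict(zip(free, map(float, s))),
                      "objective": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    kwargs = dict(fixed)
    kwargs.update(dict(zip(free, map(float, best.x))))
    params = GaussianHeterogeneityParams(**kwargs)
    grid = build_grid(params, config)
    resid_rows = []
    for _, row in data.data.iterrows():
        g = grid if row["arm"] == "pre" else evolve_composition(grid, data.course)
        pred = population_survival(g, float(row["dose_gy"]), 1)
        resid_rows.append(
            {
                "arm": row["arm"],
                "dose_gy": float(row["dose_gy"]),
                "observed": float(row["surviving_fraction"]),
                "predicted": pred,
                "log_residual": float(np.log(row["surviving_fraction"]) - np.log(pred)),
            }
        )
    summary_post = (
        summarize(evolve_composition(grid, data.course)) if data.course else None
    )
    return FitResult(
        params=params,
        free_parameters=free,
        fixed_parameters=fixed,
        objective=float(best.fun),
        residuals=pd.DataFrame(resid_rows),
        success=bool(best.success),
        message=str(best.message),
        n_evaluations=n_evals,
        summary_pre=summarize(grid),
        summary_post=summary_post,
        starts=tuple(trace),
    )


def tabulate_shift(
    params: GaussianHeterogeneityParams,
    course: FractionationSchedule,
    config: GridConfig = GridConfig(),
) -> pd.DataFrame:
    """One summary row: pre/post mean +/- SD of alpha/beta and SF2 for a course.

    This is the derived-statistics view used to compare a fitted distribution
    against published pre/post clonogenic summaries.
    """
    grid = build_grid(params, config)
    pre = summarize(grid)
    post = summarize(evolve_composition(grid, course))
    return pd.DataFrame(
        [
            {
                "total_dose_gy": course.total_dose,
                "n_fractions": course.n_fractions,
                "pre_mean_alpha_beta": pre.mean_alpha_beta_ratio,
                "pre_sd_alpha_beta": pre.sd_alpha_beta_ratio,
                "post_mean_alpha_beta": post.mean_alpha_beta_ratio,
                "post_sd_alpha_beta": post.sd_alpha_beta_ratio,
                "pre_mean_sf2": pre.mean_sf2,
                "pre_sd_sf2": pre.sd_sf2,
                "post_mean_sf2": post.mean_sf2,
                "post_sd_sf2": post.sd_sf2,
            }
        ]
    )
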