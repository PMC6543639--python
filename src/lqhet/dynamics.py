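"""Treatment-course dynamics: per-fraction selection and daily repopulation.

Each radiation fraction multiplies every cell subset's absolute count by its
own LQ surviving fraction, so resistant subsets (high SF2, low alpha/beta)
gain relative weight with every fraction — selection, not mutation.  Between
fractions the tumor repopulates once per calendar day, either uniformly (a
fixed percentage of surviving cells, default 15%/day) or with a rate coupled
to radiosensitivity:

    p(alpha, beta) = mu * exp(theta * SF2) / max exp(theta * SF2)   (resistant faster)

or with (1 - SF2) in the exponent so sensitive cells repopulate faster.  In
both coupled modes the fastest subset on the support repopulates at exactly
``mu`` per day.

Uniform repopulation never changes composition — it is a pure scaling factor
on absolute counts — so all composition results are repopulation-rate
independent under the uniform model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FractionationSchedule
from .errors import InputDomainError
from .grid import (
    DEFAULT_SF2_BIN_EDGES,
    PopulationSummary,
    RadiosensitivityGrid,
    summarize,
)

__all__ = [
    "RepopulationModel",
    "TumorState",
    "DayRecord",
    "CourseTrajectory",
    "apply_fraction",
    "repopulation_rates",
    "apply_repopulation",
    "simulate_course",
    "resistance_shift",
]

_MODES = ("uniform", "resistant_faster", "sensitive_faster")


@dataclass(frozen=True)
class RepopulationModel:
    """Daily repopulation model.

    ``uniform`` applies ``uniform_rate`` to every subset.  The coupled modes
    use ``mu`` (maximum daily repopulation fraction) and ``theta`` (coupling
    strength between SF2 and growth rate).
    """

    mode: str = "uniform"
    uniform_rate: float = 0.15
    mu: float = 0.3
    theta: float = 5.5

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise InputDomainError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (0 <= self.uniform_rate < 1):
            raise InputDomainError(f"uniform_rate must lie in [0, 1), got {self.uniform_rate}")
        if self.mu < 0 or self.theta < 0:
            raise InputDomainError("mu and theta must be >= 0")

    @classmethod
    def uniform(cls, rate: float = 0.15) -> "RepopulationModel":
        return cls(mode="uniform", uniform_rate=rate)

    @classmethod
    def none(cls) -> "RepopulationModel":
        return cls(mode="uniform", uniform_rate=0.0)

    @classmethod
    def resistant_faster(cls, mu: float = 0.3, theta: float = 5.5) -> "RepopulationModel":
        return cls(mode="resistant_faster", mu=mu, theta=theta)

    @classmethod
    def sensitive_faster(cls, mu: float = 0.3, theta: float = 5.5) -> "RepopulationModel":
        return cls(mode="sensitive_faster", mu=mu, theta=theta)

    def as_dict(self) -> dict:
        return {"mode": self.mode, "uniform_rate": self.uniform_rate,
                "mu": self.mu, "theta": self.theta}


@dataclass(frozen=True)
class TumorState:
    """Grid composition plus an absolute clonogen count.

    Counts are continuous expected values; per-cell counts are
    ``density * total_cells``.
    """

    grid: RadiosensitivityGrid
    total_cells: float = 1e10
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.total_cells > 0):
            raise InputDomainError(f"total_cells must be > 0, got {self.total_cells}")

    @property
    def cell_counts(self) -> np.ndarray:
        return self.grid.density * self.total_cells


def apply_fraction(state: TumorState, dose: float) -> TumorState:
    """Deliver one instantaneous fraction of ``dose`` Gy.

    Every subset's count is multiplied by its own surviving fraction; the
    composition is re-derived from the surviving counts.
    """
    if dose <= 0:
        raise InputDomainError(f"fraction dose must be > 0, got {dose}")
    sf = state.grid.survival_weights(dose, 1)
    surviving_mass = float((state.grid.density * sf).sum())
    return replace(
        state,
        grid=state.grid.reweighted(sf),
        total_cells=state.total_cells * surviving_mass,
    )


def repopulation_rates(
    grid: RadiosensitivityGrid, model: RepopulationModel
) -> np.ndarray:
    """Per-cell daily repopulation rate map (zero off support)."""
    if not grid.support.any():
        raise InputDomainError("grid has empty support")
    if model.mode == "uniform":
        return np.where(grid.support, model.uniform_rate, 0.0)
    s2 = grid.sf2
    x = s2 if model.mode == "resistant_faster" else 1.0 - s2
    expo = np.where(grid.support, np.exp(model.theta * x), 0.0)
    return model.mu * expo / expo.max()


def apply_repopulation(state: TumorState, model: RepopulationModel) -> TumorState:
    """Advance the tumor by one calendar day of repopulation.

    Each subset's count is multiplied by (1 + its daily rate).  Uniform
    repopulation leaves the composition bit-identical (pure scaling).
    """
    if model.mode == "uniform":
        return replace(state, total_cells=state.total_cells * (1.0 + model.uniform_rate))
    growth = 1.0 + repopulation_rates(state.grid, model)
    new_mass = float((state.grid.density * np.where(state.grid.support, growth, 0.0)).sum())
    return replace(
        state,
        grid=state.grid.reweighted(np.where(state.grid.support, growth, 0.0)),
        total_cells=state.total_cells * new_mass,
    )


@dataclass(frozen=True)
class DayRecord:
    day: int
    fraction_index: int | None
    dose: float | None
    total_cells: float
    summary: PopulationSummary


@dataclass(frozen=True)
class CourseTrajectory:
    """Day-indexed record of a simulated course.

    ``records[0]`` is the pre-treatment state (day 0); subsequent records are
    end-of-day states after that day's fraction (if any) and repopulation.
    """

    records: tuple[DayRecord, ...]
    schedule: FractionationSchedule
    model: RepopulationModel

    @property
    def initial(self) -> DayRecord:
        return self.records[0]

    @property
    def final(self) -> DayRecord:
        return self.records[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "day": r.day,
                "fraction_index": r.fraction_index,
                "dose_gy": r.dose,
                "total_cells": r.total_cells,
                "mean_sf2": r.summary.mean_sf2,
                "sd_sf2": r.summary.sd_sf2,
                "mean_alpha_beta": r.summary.mean_alpha_beta_ratio,
                "sd_alpha_beta": r.summary.sd_alpha_beta_ratio,
            }
            for (lo, hi), v in r.summary.bin_fractions.items():
                row[f"sf2_bin_{lo:g}_{hi:g}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "schedule": self.schedule.to_spec(),
            "n_fractions": self.schedule.n_fractions,
            "total_dose_gy": self.schedule.total_dose,
            "repopulation": self.model.as_dict(),
            "initial_total_cells": self.initial.total_cells,
        }

    def write_manifest(self, path: str | Path, extra: dict | None = None) -> None:
        m = self.manifest()
        if extra:
            m.update(extra)
        Path(path).write_text(json.dumps(m, indent=2))


def simulate_course(
    initial: TumorState,
    schedule: FractionationSchedule,
    model: RepopulationModel = RepopulationModel.uniform(),
    bin_edges: Sequence[float] = DEFAULT_SF2_BIN_EDGES,
) -> CourseTrajectory:
    """Evolve a tumor through a fractionation calendar.

    For each calendar day from 1 to the last fraction day: deliver the day's
    fraction (if scheduled), then apply one day of repopulation (weekends
    included).  End-of-course is the last fraction's day after that day's
    repopulation.
    """
    doses = schedule.doses_by_day
    state = initial
    records = [
        DayRecord(0, None, None, state.total_cells, summarize(state.grid, bin_edges))
    ]
    fraction_index = 0
    for day in range(1, schedule.last_day + 1):
        dose = doses.get(day)
        if dose is not None:
            fraction_index += 1
            state = apply_fraction(state, dose)
        state = apply_repopulation(state, model)
        records.append(
            DayRecord(
                day,
                fraction_index if dose is not None else None,
                dose,
                state.total_cells,
                summarize(state.grid, bin_edges),
            )
        )
    return CourseTrajectory(tuple(records), schedule, model)


def resistance_shift(trajectory: CourseTrajectory) -> pd.DataFrame:
    """Per-day shifts of mean SF2 and mean alpha/beta vs pre-treatment.

    Positive SF2 shift / negative alpha/beta shift indicate selection toward
    radioresistance.  Day 0 has both shifts exactly 0 by construction.
    """
    base = trajectory.initial.summary
    return pd.DataFrame(
        {
            "day": [r.day for r in trajectory.records],
            "sf2_shift": [r.summary.mean_sf2 - base.mean_sf2 for r in trajectory.records],
            "alpha_beta_shift": [
                r.summary.mean_alpha_beta_ratio - base.mean_alpha_beta_ratio
                for r in trajectory.records
            ],
        }
    )
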