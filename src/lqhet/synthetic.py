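"""Synthetic clonogenic-assay data and named fixture tumors.

Everything here is generated from known ground truth so that fitting and
simulation can be exercised and scored without any external data.  The assay
generator emulates the structure of published pre/post clonogenic
experiments: surviving fractions at graded doses (default 2-10 Gy) for a
parental line and for a line re-grown after a conditioning course, with
multiplicative (lognormal) measurement noise and replicate wells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FractionationSchedule
from .dynamics import TumorState
from .errors import InputDomainError
from .fitting import AssayMeasurementSet, predict_assay
from .grid import GaussianHeterogeneityParams, GridConfig, RadiosensitivityGrid, build_grid

__all__ = ["SyntheticAssayConfig", "generate_assay", "fixture_tumors", "FIXTURE_PARAMS"]


@dataclass(frozen=True)
class SyntheticAssayConfig:
    """Ground truth and noise settings for a synthetic clonogenic experiment.

    ``noise_sd_log`` is the standard deviation of zero-mean Gaussian noise on
    log surviving fraction (lognormal multiplicative noise on SF), the
    conventional error model for clonogenic assays.
    """

    true_params: GaussianHeterogeneityParams
    course: FractionationSchedule | None = None
    dose_points: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    replicates: int = 3
    noise_sd_log: float = 0.05
    seed: int = 0
    grid_config: GridConfig = field(default_factory=GridConfig)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InputDomainError("replicates must be >= 1")
        if self.noise_sd_log < 0:
            raise InputDomainError("noise_sd_log must be >= 0")
        if any(d <= 0 for d in self.dose_points):
            raise InputDomainError("dose points must be > 0 Gy")


def generate_assay(config: SyntheticAssayConfig) -> tuple[AssayMeasurementSet, dict]:
    """Draw a synthetic measurement set plus its ground-truth sidecar record.

    Noiseless predictions come from the forward model; each replicate is
    multiplied by exp(eps), eps ~ N(0, noise_sd_log), then clamped to (0, 1].
    All draws derive from a single seeded generator, so a fixed seed yields
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    arms: list[tuple[str, FractionationSchedule | None]] = [("pre", None)]
    if config.course is not None:
        arms.append(("post", config.course))

    rows = []
    truth_predictions = {}
    for arm, course in arms:
        pred = predict_assay(
            config.true_params, config.grid_config, course, config.dose_points
        )
        truth_predictions[arm] = dict(zip(map(float, config.dose_points), map(float, pred)))
        for dose, p in zip(config.dose_points, pred):
            for rep in range(1, config.replicates + 1):
                eps = rng.normal(0.0, config.noise_sd_log) if config.noise_sd_log > 0 else 0.0
                sf = min(float(p * np.exp(eps)), 1.0)
                rows.append(
                    {
                        "dose_gy": float(dose),
                        "surviving_fraction": sf,
                        "arm": arm,
                        "replicate": rep,
                    }
                )
    data = AssayMeasurementSet(pd.DataFrame(rows), course=config.course)
    truth = {
        "true_params": config.true_params.as_dict(),
        "course": config.course.to_spec() if config.course else None,
        "dose_points": list(map(float, config.dose_points)),
        "replicates": config.replicates,
        "noise_sd_log": config.noise_sd_log,
        "seed": config.seed,
        "grid_config": {
            "cutoff": config.grid_config.cutoff,
            "resolution": config.grid_config.resolution,
        },
        "noiseless_predictions": truth_predictions,
    }
    return data, truth


def write_assay(
    data: AssayMeasurementSet, truth: dict, csv_path: str | Path
) -> None:
    """Write the measurement CSV plus a ground-truth JSON sidecar next to it."""
    csv_path = Path(csv_path)
    data.to_csv(csv_path)
    csv_path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


#: Published-caption parameter sets for the named distributions D1-D6.
#: D1 is the esophageal-line fit; D2-D4 move the center (same widths);
#: D5/D6 narrow/widen sigma_alpha at the D4 center (alpha/beta = 10 Gy).
FIXTURE_PARAMS: dict[str, GaussianHeterogeneityParams] = {
    "D1": GaussianHeterogeneityParams(0.40, 0.020, 6.5e-2, 3.5e-3),
    "D2": GaussianHeterogeneityParams(0.40, 0.040, 6.5e-2, 3.5e-3),
    "D3": GaussianHeterogeneityParams(0.25, 0.020, 6.5e-2, 3.5e-3),
    "D4": GaussianHeterogeneityParams(0.33, 0.033, 6.5e-2, 3.5e-3),
    "D5": GaussianHeterogeneityParams(0.33, 0.033, 4.5e-2, 3.5e-3),
    "D6": GaussianHeterogeneityParams(0.33, 0.033, 8.5e-2, 3.5e-3),
}


def fixture_tumors(
    config: GridConfig = GridConfig(), total_cells: float = 1e10
) -> dict[str, TumorState]:
    """Named library of ground-truth tumors.

    Returns the six Gaussian distributions D1-D6 plus a homogeneous control
    (a point mass at the D1 center — selection cannot change it) and a
    two-subset toy (equal parts alpha = 0.2 and 0.4 at beta = 0.02) whose
    dynamics can be checked by hand.
    """
    tumors = {
        name: TumorState(build_grid(p, config), total_cells, label=name)
        for name, p in FIXTURE_PARAMS.items()
    }
    tumors["homogeneous"] = TumorState(
        RadiosensitivityGrid.from_points([(0.40, 0.020)]), total_cells, label="homogeneous"
    )
    tumors["two_subset"] = TumorState(
        RadiosensitivityGrid.from_points([(0.20, 0.020), (0.40, 0.020)], [0.5, 0.5]),
        total_cells,
        label="two_subset",
    )
    return tumors
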