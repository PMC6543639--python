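"""Discretized intratumoral radiosensitivity distributions.

A tumor is modelled as a continuum of cell subsets, each with its own LQ
coefficients (alpha, beta).  The innate spread is an axis-aligned bivariate
Gaussian weight

    f(alpha, beta) = exp(-((alpha-alpha_c)^2 / (2 sigma_alpha^2)
                          + (beta-beta_c)^2 / (2 sigma_beta^2)))

with peak value 1 at the center.  Support is truncated where the
unnormalized weight falls below a cutoff (default 1e-2), i.e. inside the
level-set ellipse of standardized squared radius 2 ln(1/cutoff), and the
remaining weights are renormalized to sum to 1 so the grid represents 100%
of the tumor cell population.

The grid is the package's central container: treatment dynamics re-weight
its density, and all population summaries (mean/SD of the alpha/beta ratio
and of SF2, SF2-bin compositions, population-average survival) are
density-weighted sums over its cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridConstructionError, InputDomainError

__all__ = [
    "GaussianHeterogeneityParams",
    "GridConfig",
    "RadiosensitivityGrid",
    "PopulationSummary",
    "build_grid",
    "summarize",
    "bin_fractions",
    "population_survival",
    "DEFAULT_SF2_BIN_EDGES",
]

#: Default SF2 composition bins. The outer interior edges (0.24, 0.47, 0.55)
#: delimit the canonical "sensitive" and "resistant" subsets; edges are
#: user-configurable since finer compositions are study-specific.
DEFAULT_SF2_BIN_EDGES: tuple[float, ...] = (0.0, 0.24, 0.47, 0.55, 1.0)

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class GaussianHeterogeneityParams:
    """Center and spread of the innate (alpha, beta) distribution.

    All four parameters are positive.  ``alpha_c``/``beta_c`` are the modal
    LQ coefficients; ``sigma_alpha``/``sigma_beta`` control the width of the
    intratumoral spread.
    """

    alpha_c: float
    beta_c: float
    sigma_alpha: float
    sigma_beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_c", "beta_c", "sigma_alpha", "sigma_beta"):
            if not (getattr(self, name) > 0):
                raise InputDomainError(f"{name} must be > 0, got {getattr(self, name)}")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_c": self.alpha_c,
            "beta_c": self.beta_c,
            "sigma_alpha": self.sigma_alpha,
            "sigma_beta": self.sigma_beta,
        }


@dataclass(frozen=True)
class GridConfig:
    """Discretization settings: truncation cutoff and points per axis."""

    cutoff: float = 1e-2
    resolution: int = 201

    def __post_init__(self) -> None:
        if not (0 < self.cutoff < 1):
            raise InputDomainError(f"cutoff must lie in (0, 1), got {self.cutoff}")
        if self.resolution < 3:
            raise InputDomainError(f"resolution must be >= 3, got {self.resolution}")

    @property
    def radius(self) -> float:
        """Truncation radius in standardized coordinates, sqrt(2 ln(1/cutoff))."""
        return math.sqrt(2.0 * math.log(1.0 / self.cutoff))


class RadiosensitivityGrid:
    """Normalized density over a rectangular (alpha, beta) lattice.

    Attributes
    ----------
    alpha_axis, beta_axis : 1-D arrays of cell coordinates (sorted).
    density : 2-D array, shape (len(alpha_axis), len(beta_axis)); sums to 1.
    support : boolean mask frozen at construction; the truncation cutoff is
        applied once and never re-applied by later re-weighting.
    sf2 : per-cell surviving fraction at 2 Gy, exp(-2 (alpha + 2 beta)).
    """

    def __init__(
        self,
        alpha_axis: np.ndarray,
        beta_axis: np.ndarray,
        density: np.ndarray,
        support: np.ndarray | None = None,
        params: GaussianHeterogeneityParams | None = None,
        config: GridConfig | None = None,
    ) -> None:
        alpha_axis = np.asarray(alpha_axis, dtype=float)
        beta_axis = np.asarray(beta_axis, dtype=float)
        density = np.asarray(density, dtype=float)
        if density.shape != (alpha_axis.size, beta_axis.size):
            raise GridConstructionError("density shape must be (n_alpha, n_beta)")
        if np.any(density < 0):
            raise GridConstructionError("density must be non-negative")
        total = density.sum()
        if not np.isfinite(total) or total <= 0:
            raise GridConstructionError("density must have positive finite mass")
        self.alpha_axis = alpha_axis
        self.beta_axis = beta_axis
        self.density = density / total
        self.support = (self.density > 0) if support is None else np.asarray(support, bool)
        if np.any(self.beta_mesh[self.support] <= 0):
            raise GridConstructionError("supported cells must have beta > 0")
        self.params = params
        self.config = config

    # -- lazily derived meshes ---------------------------------------------
    @property
    def alpha_mesh(self) -> np.ndarray:
        return np.broadcast_to(self.alpha_axis[:, None], self.shape)

    @property
    def beta_mesh(self) -> np.ndarray:
        return np.broadcast_to(self.beta_axis[None, :], self.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.alpha_axis.size, self.beta_axis.size)

    @property
    def sf2(self) -> np.ndarray:
        return np.exp(-2.0 * (self.alpha_mesh + 2.0 * self.beta_mesh))

    @property
    def alpha_beta_ratio(self) -> np.ndarray:
        """Per-cell alpha/beta (Gy); off-support cells are masked to 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.support, self.alpha_mesh / self.beta_mesh, 0.0)
        return r

    # -- operations ---------------------------------------------------------
    def survival_weights(self, dose: float, n_fractions: float = 1) -> np.ndarray:
        """Per-cell LQ surviving fraction exp(-n d (alpha + beta d))."""
        if dose < 0 or n_fractions < 0:
            raise InputDomainError("dose and fraction count must be >= 0")
        e = n_fractions * dose * (self.alpha_mesh + self.beta_mesh * dose)
        return np.where(self.support, np.exp(-e), 0.0)

    def reweighted(self, multiplier: np.ndarray) -> "RadiosensitivityGrid":
        """Return a new grid with density ∝ density * multiplier, renormalized.

        The frozen support is preserved: truncation is never re-applied.
        """
        m = np.asarray(multiplier, dtype=float)
        new = self.density * m
        if np.any(new < 0):
            raise InputDomainError("re-weighting multiplier must be non-negative")
        return RadiosensitivityGrid(
            self.alpha_axis, self.beta_axis, new, support=self.support,
            params=self.params, config=self.config,
        )

    def weighted_mean_params(self) -> tuple[float, float]:
        """Density-weighted mean (alpha, beta) of the population."""
        return (
            float((self.density * self.alpha_mesh).sum()),
            float((self.density * self.beta_mesh).sum()),
        )

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table of supported cells: alpha, beta, density."""
        ii, jj = np.nonzero(self.support)
        return pd.DataFrame(
            {
                "alpha": self.alpha_axis[ii],
                "beta": self.beta_axis[jj],
                "density": self.density[ii, jj],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        header = {
            "params": self.params.as_dict() if self.params else None,
            "cutoff": self.config.cutoff if self.config else None,
            "resolution": self.config.resolution if self.config else None,
        }
        with open(path, "w", newline="") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadiosensitivityGrid":
        with open(path) as fh:
            first = fh.readline()
            header = json.loads(first[1:]) if first.startswith("#") else {}
            if not first.startswith("#"):
                fh.seek(0)
            df = pd.read_csv(fh)
        alpha_axis = np.unique(df["alpha"].to_numpy())
        beta_axis = np.unique(df["beta"].to_numpy())
        density = np.zeros((alpha_axis.size, beta_axis.size))
        ai = np.searchsorted(alpha_axis, df["alpha"].to_numpy())
        bi = np.searchsorted(beta_axis, df["beta"].to_numpy())
        density[ai, bi] = df["density"].to_numpy()
        params = (
            GaussianHeterogeneityParams(**header["params"]) if header.get("params") else None
        )
        config = (
            GridConfig(cutoff=header["cutoff"], resolution=header["resolution"])
            if header.get("cutoff") is not None
            else None
        )
        return cls(alpha_axis, beta_axis, density, params=params, config=config)

    @classmethod
    def from_points(
        cls, points: Sequence[tuple[float, float]], weights: Sequence[float] | None = None
    ) -> "RadiosensitivityGrid":
        """Build a small discrete grid from explicit (alpha, beta) subsets.

        Convenience constructor for homogeneous controls and few-subset toys.
        """
        alphas = np.unique([p[0] for p in points])
        betas = np.unique([p[1] for p in points])
        density = np.zeros((alphas.size, betas.size))
        w = np.ones(len(points)) if weights is None else np.asarray(weights, float)
        for (a, b), wi in zip(points, w):
            density[np.searchsorted(alphas, a), np.searchsorted(betas, b)] += wi
        return cls(alphas, betas, density)


@dataclass(frozen=True)
class PopulationSummary:
    """Density-weighted population statistics of a radiosensitivity grid."""

    mean_alpha_beta_ratio: float
    sd_alpha_beta_ratio: float
    mean_sf2: float
    sd_sf2: float
    bin_fractions: Mapping[tuple[float, float], float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mean_alpha_beta_ratio": self.mean_alpha_beta_ratio,
            "sd_alpha_beta_ratio": self.sd_alpha_beta_ratio,
            "mean_sf2": self.mean_sf2,
            "sd_sf2": self.sd_sf2,
            "bin_fractions": [
                {"sf2_lo": lo, "sf2_hi": hi, "fraction": v}
                for (lo, hi), v in self.bin_fractions.items()
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def build_grid(
    params: GaussianHeterogeneityParams, config: GridConfig = GridConfig()
) -> RadiosensitivityGrid:
    """Discretize, truncate and normalize the Gaussian radiosensitivity spread.

    The lattice is a uniform ``resolution x resolution`` grid over the
    bounding box of the cutoff ellipse.  Cell weights are point evaluations
    of the unnormalized Gaussian (midpoint quadrature), zeroed where the
    weight falls below the cutoff and renormalized to sum to 1.

    Raises
    ------
    GridConstructionError
        If the truncation support would cross beta <= 0, or no cell survives
        the cutoff at the requested resolution.
    """
    r = config.radius
    if params.beta_c - r * params.sigma_beta <= 0:
        raise GridConstructionError(
            "truncation support crosses beta <= 0: "
            f"beta_c - {r:.3f}*sigma_beta = {params.beta_c - r * params.sigma_beta:.3g}"
        )
    a = np.linspace(params.alpha_c - r * params.sigma_alpha,
                    params.alpha_c + r * params.sigma_alpha, config.resolution)
    b = np.linspace(params.beta_c - r * params.sigma_beta,
                    params.beta_c + r * params.sigma_beta, config.resolution)
    A, B = np.meshgrid(a, b, indexing="ij")
    f = np.exp(
        -(
            (A - params.alpha_c) ** 2 / (2.0 * params.sigma_alpha**2)
            + (B - params.beta_c) ** 2 / (2.0 * params.sigma_beta**2)
        )
    )
    support = f >= config.cutoff
    f = np.where(support, f, 0.0)
    if not support.any():
        raise GridConstructionError("empty support: resolution too coarse for the cutoff")
    return RadiosensitivityGrid(a, b, f, support=support, params=params, config=config)


def summarize(
    grid: RadiosensitivityGrid,
    bin_edges: Sequence[float] = DEFAULT_SF2_BIN_EDGES,
) -> PopulationSummary:
    """Density-weighted mean/SD of the per-cell alpha/beta ratio and SF2.

    The mean ratio is the expectation of the per-cell ratio E[alpha/beta]
    (not the ratio of expectations), matching how per-subset summaries are
    pooled across a heterogeneous population.
    """
    _assert_normalized(grid)
    w = grid.density
    ratio = grid.alpha_beta_ratio
    s2 = grid.sf2
    mr = float((w * ratio).sum())
    ms = float((w * np.where(grid.support, s2, 0.0)).sum())
    sr = math.sqrt(max(float((w * (ratio - mr) ** 2)[grid.support].sum()), 0.0))
    ss = math.sqrt(max(float((w * (s2 - ms) ** 2)[grid.support].sum()), 0.0))
    return PopulationSummary(
        mean_alpha_beta_ratio=mr,
        sd_alpha_beta_ratio=sr,
        mean_sf2=ms,
        sd_sf2=ss,
        bin_fractions=bin_fractions(grid, bin_edges),
    )


def bin_fractions(
    grid: RadiosensitivityGrid, edges: Sequence[float]
) -> dict[tuple[float, float], float]:
    """Population fractions in SF2 intervals.

    Intervals are half-open ``[lo, hi)`` except the last, which is closed at
    its upper edge so SF2 = 1 is counted.  Fractions sum to the grid's total
    mass (1 for a normalized grid).
    """
    e = list(edges)
    if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
        raise InputDomainError("bin edges must be strictly increasing with >= 2 entries")
    if e[0] < 0 or e[-1] > 1:
        raise InputDomainError("bin edges must lie within [0, 1]")
    s2 = grid.sf2
    out: dict[tuple[float, float], float] = {}
    for i, (lo, hi) in enumerate(zip(e, e[1:])):
        last = i == len(e) - 2
        sel = (s2 >= lo) & ((s2 <= hi) if last else (s2 < hi)) & grid.support
        out[(lo, hi)] = float(grid.density[sel].sum())
    return out


def population_survival(
    grid: RadiosensitivityGrid, dose: float, n_fractions: float = 1
) -> float:
    """Population-average surviving fraction: sum_cells density * SF(d)^n.

    This is the model's prediction for a clonogenic assay performed on the
    mixed population with its current composition.
    """
    _assert_normalized(grid)
    return float((grid.density * grid.survival_weights(dose, n_fractions)).sum())


def _assert_normalized(grid: RadiosensitivityGrid) -> None:
    total = grid.density.sum()
    if abs(total - 1.0) > 1e-9:
        raise InputDomainError(f"grid density must sum to 1, got {total!r}")
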