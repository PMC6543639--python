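"""Closed-form linear-quadratic (LQ) radiobiology.

The LQ model describes clonogenic survival after ``n`` fractions of dose
``d`` (Gy) as ``SF = exp(-n d (alpha + beta d))``, where ``alpha`` (Gy^-1)
and ``beta`` (Gy^-2) are tissue radiosensitivity coefficients.  This module
provides the survival curve, the per-course effect ``E = n d (alpha + beta d)``,
the biologically effective dose ``BED = n d (1 + d / (alpha/beta))`` used to
compare fractionation regimens, and calendar construction for conventional
5-days-on / 2-days-off treatment weeks.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputDomainError

__all__ = [
    "LQParams",
    "FractionationSchedule",
    "effect",
    "survival_fraction",
    "sf2",
    "bed",
    "isoeffective_fractions",
    "build_calendar",
]


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity coefficients.

    Parameters
    ----------
    alpha : float
        Linear coefficient (Gy^-1), one-track lethal damage. Must be >= 0.
    beta : float
        Quadratic coefficient (Gy^-2), two-track damage. Must be > 0 so
        that the alpha/beta ratio is always defined.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha >= 0.0):
            raise InputDomainError(f"alpha must be >= 0, got {self.alpha}")
        if not (self.beta > 0.0):
            raise InputDomainError(f"beta must be > 0, got {self.beta}")

    @property
    def alpha_beta_ratio(self) -> float:
        """The alpha/beta ratio in Gy (fractionation-sensitivity summary)."""
        return self.alpha / self.beta


def effect(params: LQParams, dose: float, n_fractions: float = 1) -> float:
    """Radiobiological effect ``E = n d (alpha + beta d)`` (dimensionless)."""
    _check_dose_fractions(dose, n_fractions)
    return n_fractions * dose * (params.alpha + params.beta * dose)


def survival_fraction(params: LQParams, dose: float, n_fractions: float = 1) -> float:
    """Surviving fraction ``exp(-n d (alpha + beta d))`` after ``n`` fractions of ``d`` Gy."""
    return math.exp(-effect(params, dose, n_fractions))


def sf2(params: LQParams) -> float:
    """Surviving fraction at a single 2 Gy dose, ``exp(-2 (alpha + 2 beta))``.

    SF2 is the standard scalar radiosensitivity summary used throughout
    clonogenic-assay work; high SF2 means radioresistant.
    """
    return survival_fraction(params, 2.0, 1)


def bed(n_fractions: float, dose: float, alpha_beta_ratio: float) -> float:
    """Biologically effective dose ``n d (1 + d / (alpha/beta))`` in Gy."""
    if alpha_beta_ratio <= 0:
        raise InputDomainError(f"alpha/beta ratio must be > 0, got {alpha_beta_ratio}")
    if dose < 0:
        raise InputDomainError(f"dose must be >= 0, got {dose}")
    return n_fractions * dose * (1.0 + dose / alpha_beta_ratio)


def isoeffective_fractions(target_bed: float, dose: float, alpha_beta_ratio: float) -> float:
    """Real-valued fraction count delivering ``target_bed`` at ``dose`` Gy per fraction.

    Returns ``target_bed / (d (1 + d/(alpha/beta)))``.  Callers wanting a
    deliverable schedule round to the nearest integer; the rounded schedule's
    BED is then only approximately the target.
    """
    if target_bed <= 0:
        raise InputDomainError(f"target BED must be > 0, got {target_bed}")
    if dose <= 0:
        raise InputDomainError(f"dose must be > 0, got {dose}")
    if alpha_beta_ratio <= 0:
        raise InputDomainError(f"alpha/beta ratio must be > 0, got {alpha_beta_ratio}")
    return target_bed / (dose * (1.0 + dose / alpha_beta_ratio))


def _check_dose_fractions(dose: float, n_fractions: float) -> None:
    if dose < 0:
        raise InputDomainError(f"dose must be >= 0, got {dose}")
    if n_fractions < 0:
        raise InputDomainError(f"fraction count must be >= 0, got {n_fractions}")


_SPEC_RE = re.compile(r"^\s*(\d+)\s*x\s*([0-9.]+)\s*(?::\s*(weekday|daily)\s*)?$")


@dataclass(frozen=True)
class FractionationSchedule:
    """A calendar of instantaneous dose events.

    ``events`` is an ordered tuple of ``(calendar_day, dose_gy)`` pairs with
    strictly increasing positive day indices.  Day 1 is a treatment day (a
    Monday); in the weekday pattern days 6-7 of each week are the weekend.
    """

    events: tuple[tuple[int, float], ...]
    pattern: str = field(default="explicit", compare=False)

    def __post_init__(self) -> None:
        if not self.events:
            raise InputDomainError("schedule must contain at least one event")
        days = [d for d, _ in self.events]
        if any(d < 1 or d != int(d) for d in days):
            raise InputDomainError("calendar days must be positive integers")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InputDomainError("calendar days must be strictly increasing")
        if any(dose <= 0 for _, dose in self.events):
            raise InputDomainError("event doses must be > 0 Gy")

    # -- derived quantities -------------------------------------------------
    @property
    def n_fractions(self) -> int:
        return len(self.events)

    @property
    def total_dose(self) -> float:
        return sum(dose for _, dose in self.events)

    @property
    def dose_per_fraction(self) -> float | None:
        """Dose per fraction if the schedule is uniform, else None."""
        doses = {dose for _, dose in self.events}
        return next(iter(doses)) if len(doses) == 1 else None

    @property
    def last_day(self) -> int:
        return self.events[-1][0]

    @property
    def doses_by_day(self) -> dict[int, float]:
        return {day: dose for day, dose in self.events}

    def bed(self, alpha_beta_ratio: float) -> float:
        """Total BED of the schedule (sum of per-fraction BED contributions)."""
        return sum(bed(1, dose, alpha_beta_ratio) for _, dose in self.events)

    # -- constructors -------------------------------------------------------
    @classmethod
    def weekday(cls, n_fractions: int, dose: float) -> "FractionationSchedule":
        """5-on/2-off weekly calendar: fractions on days 1-5, 8-12, 15-19, ..."""
        if n_fractions < 1:
            raise InputDomainError("n_fractions must be >= 1")
        days = [7 * (i // 5) + (i % 5) + 1 for i in range(n_fractions)]
        return cls(tuple((d, float(dose)) for d in days), pattern="weekday")

    @classmethod
    def daily(cls, n_fractions: int, dose: float) -> "FractionationSchedule":
        if n_fractions < 1:
            raise InputDomainError("n_fractions must be >= 1")
        return cls(tuple((i + 1, float(dose)) for i in range(n_fractions)), pattern="daily")

    @classmethod
    def from_spec(cls, spec: str) -> "FractionationSchedule":
        """Parse a compact spec string such as ``"35x2.0:weekday"`` or ``"10x3.0:daily"``.

        The pattern suffix defaults to ``weekday``.
        """
        m = _SPEC_RE.match(spec)
        if not m:
            raise InputDomainError(
                f"unparseable schedule spec {spec!r}; expected 'NxD[:weekday|daily]'"
            )
        n, dose, pattern = int(m.group(1)), float(m.group(2)), m.group(3) or "weekday"
        return cls.weekday(n, dose) if pattern == "weekday" else cls.daily(n, dose)

    def to_spec(self) -> str:
        d = self.dose_per_fraction
        if self.pattern in ("weekday", "daily") and d is not None:
            return f"{self.n_fractions}x{d:g}:{self.pattern}"
        return ";".join(f"{day}:{dose:g}" for day, dose in self.events)

    # -- serialization ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["day", "dose_gy"])
            writer.writerows(self.events)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FractionationSchedule":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise InputDomainError(f"schedule CSV {path} is empty")
        events = tuple((int(r["day"]), float(r["dose_gy"])) for r in rows)
        return cls(events)


def build_calendar(
    n_fractions: int,
    dose: float,
    pattern: str | Sequence[int] = "weekday_5on2off",
) -> FractionationSchedule:
    """Build a fractionation calendar.

    ``pattern`` is ``"weekday_5on2off"`` (alias ``"weekday"``), ``"daily"``,
    or an explicit strictly increasing list of calendar days of length
    ``n_fractions``.
    """
    if isinstance(pattern, str):
        if pattern in ("weekday_5on2off", "weekday"):
            return FractionationSchedule.weekday(n_fractions, dose)
        if pattern == "daily":
            return FractionationSchedule.daily(n_fractions, dose)
        raise InputDomainError(f"unknown calendar pattern {pattern!r}")
    days: Iterable[int] = pattern
    events = tuple((int(d), float(dose)) for d in days)
    if len(events) != n_fractions:
        raise InputDomainError("explicit day list length must equal n_fractions")
    return FractionationSchedule(events)
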