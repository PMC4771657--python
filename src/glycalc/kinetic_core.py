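"""First-principles erythrocyte-cohort glycation engine.

Each red blood cell starts life unglycated; its non-glycated haemoglobin
fraction h(t) decays as dh/dt = -k * h * AG(t), so a cell of age ``a`` that
lived through the glucose history AG carries a glycated fraction

    g(a) = 1 - exp(-k * integral of AG over the cell's lifetime).

The circulating population is uniformly age-distributed on [0, LS]; the
blood-level HbA1c is the age-average of g, mapped onto the NGSP percent
scale by the kinetic model's scale and offset. For a glucose history that
is constant at eAG this average collapses to the closed form
``1 - (1 - exp(-x))/x`` with ``x = k*LS*eAG`` — the engine therefore acts
as an independent check on that formula, and extends it to arbitrary
piecewise-constant (time-varying) glucose.

Age convention: a cell of age ``a`` at the test instant has experienced the
most recent ``a`` seconds of the trajectory. This is what makes recent
months weigh more: they are seen by every cohort, the earliest month only
by the oldest cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .errors import CoverageError, DomainError, NumericalError
from .glycation_models import (
    GlucoseValue,
    KineticParams,
    MonthlyProfile,
    WeightScheme,
)

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class GlucoseTrajectory:
    """Piecewise-constant glucose history, earliest segment first.

    Levels are stored in mmol/l (the unit of the rate constant k);
    durations in seconds. The trajectory ends at the test instant.
    """

    durations_s: tuple[float, ...]
    levels_mmoll: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.durations_s) != len(self.levels_mmoll) or not self.durations_s:
            raise DomainError("trajectory needs matching, non-empty durations and levels")
        if any(d <= 0 for d in self.durations_s):
            raise DomainError("segment durations must be strictly positive")
        if any(lvl < 0 or not math.isfinite(lvl) for lvl in self.levels_mmoll):
            raise DomainError("glucose levels must be finite and >= 0")

    @classmethod
    def from_segments(
        cls, segments: Iterable[tuple[float, GlucoseValue | float]]
    ) -> "GlucoseTrajectory":
        """Build from (duration_s, level) pairs; bare floats are mmol/l."""
        durations, levels = [], []
        for duration, level in segments:
            durations.append(float(duration))
            levels.append(level.mmoll if isinstance(level, GlucoseValue) else float(level))
        return cls(tuple(durations), tuple(levels))

    @classmethod
    def from_monthly_profile(
        cls,
        profile: MonthlyProfile,
        window_days: float = 30.0,
        pad_to_days: float | None = None,
    ) -> "GlucoseTrajectory":
        """One segment of ``window_days`` per month, earliest first.

        A 3-month profile covers 90 days — less than the 120-day life span —
        so padding must be requested *explicitly* via ``pad_to_days``: the
        earliest month's level is extended backward to reach that total
        duration. Silent padding would change results, so there is none.
        """
        durations = [window_days * SECONDS_PER_DAY] * len(profile)
        levels = [m.mmoll for m in profile.months]
        if pad_to_days is not None:
            deficit = pad_to_days * SECONDS_PER_DAY - sum(durations)
            if deficit > 0:
                durations.insert(0, deficit)
                levels.insert(0, levels[0])
        return cls(tuple(durations), tuple(levels))

    @property
    def total_duration_s(self) -> float:
        return sum(self.durations_s)

    def exposure(self, age_s: float) -> float:
        """Integral of glucose (mmol*s/l) over the most recent ``age_s`` seconds."""
        if age_s < 0:
            raise DomainError(f"cell age must be >= 0, got {age_s}")
        if age_s > self.total_duration_s * (1 + 1e-12):
            raise DomainError(
                f"cell age {age_s} s exceeds trajectory coverage "
                f"{self.total_duration_s} s"
            )
        remaining = min(age_s, self.total_duration_s)
        total = 0.0
        for duration, level in zip(reversed(self.durations_s), reversed(self.levels_mmoll)):
            step = min(remaining, duration)
            total += level * step
            remaining -= step
            if remaining <= 0:
                break
        return total


@dataclass(frozen=True)
class CohortResult:
    """Age-averaged glycated fraction and its NGSP percent equivalent."""

    glycated_fraction: float
    hba1c_percent: float


def cell_glycated_fraction(
    age_s: float, trajectory: GlucoseTrajectory, k: float
) -> float:
    """Glycated fraction of one cell of the given age: 1 - exp(-k * exposure)."""
    return -math.expm1(-k * trajectory.exposure(age_s))


def _exact_mean_fraction(trajectory: GlucoseTrajectory, params: KineticParams) -> float:
    """Exact age-average of the glycated fraction over [0, LS].

    Walking backward from the test instant, the exposure I(a) is linear in
    age within each segment with slope equal to that segment's level, so
    the mean of exp(-k*I(a)) has a closed form per segment.
    """
    ls = params.lifespan_seconds
    k = params.k
    mean_exp = 0.0  # integral of exp(-k*I(a)) da over [0, LS]
    age0 = 0.0
    exposure0 = 0.0
    for duration, level in zip(reversed(trajectory.durations_s), reversed(trajectory.levels_mmoll)):
        if age0 >= ls:
            break
        span = min(duration, ls - age0)
        base = math.exp(-k * exposure0)
        rate = k * level
        if rate * span < 1e-12:
            # level ~ 0: exp term constant over the segment (2nd order in rate*span)
            mean_exp += base * span * (1.0 - rate * span / 2.0)
        else:
            mean_exp += base * (1.0 - math.exp(-rate * span)) / rate
        exposure0 += level * span
        age0 += span
    return 1.0 - mean_exp / ls


def _midpoint_mean_fraction(
    trajectory: GlucoseTrajectory, params: KineticParams, n: int
) -> float:
    ls = params.lifespan_seconds
    step = ls / n
    total = 0.0
    for i in range(n):
        age = (i + 0.5) * step
        total += cell_glycated_fraction(age, trajectory, params.k)
    return total / n


def cohort_hba1c(
    trajectory: GlucoseTrajectory,
    params: KineticParams = KineticParams(),
    quadrature_points: int | None = None,
) -> CohortResult:
    """HbA1c of a uniformly age-distributed cohort living through ``trajectory``.

    With ``quadrature_points=None`` the per-segment exact integral is used
    (the trajectory is piecewise constant, so the age-average has a closed
    form); otherwise midpoint quadrature with that many age points.

    The trajectory must cover at least one full life span.
    """
    if trajectory.total_duration_s < params.lifespan_seconds * (1 - 1e-12):
        raise CoverageError(
            f"trajectory covers {trajectory.total_duration_s / SECONDS_PER_DAY:.1f} "
            f"days but the life span is {params.lifespan_days} days; extend it or "
            "build it with an explicit pad_to_days"
        )
    if quadrature_points is None:
        fraction = _exact_mean_fraction(trajectory, params)
    else:
        if quadrature_points < 1:
            raise DomainError("quadrature_points must be >= 1")
        fraction = _midpoint_mean_fraction(trajectory, params, quadrature_points)
    return CohortResult(
        glycated_fraction=fraction,
        hba1c_percent=params.scale_percent * fraction + params.offset_percent,
    )


def constant_trajectory(
    level: GlucoseValue | float, duration_days: float
) -> GlucoseTrajectory:
    """A single-segment trajectory (bare floats are mg/dl, the table unit)."""
    glucose = level if isinstance(level, GlucoseValue) else GlucoseValue(float(level))
    return GlucoseTrajectory((duration_days * SECONDS_PER_DAY,), (glucose.mmoll,))


def closed_form_check(eag: GlucoseValue | float, params: KineticParams = KineticParams()) -> float:
    """Cohort engine at constant glucose, exact integral — should match the
    closed form ``scale*(1-(1-e^-x)/x)+offset`` to floating-point accuracy."""
    trajectory = constant_trajectory(eag, params.lifespan_days)
    return cohort_hba1c(trajectory, params).hba1c_percent


def implied_month_weights(
    baseline: GlucoseValue | float,
    params: KineticParams = KineticParams(),
    window_days: float = 30.0,
    n_windows: int = 3,
    rel_perturbation: float = 0.01,
) -> WeightScheme:
    """How much each backward-looking window actually contributes to HbA1c.

    Around a constant ``baseline`` glucose, perturb each window's level by
    +/- ``rel_perturbation`` * baseline (central differences) and normalise
    the sensitivities over the included windows, earliest first. Quantifies
    the folk figure that the most recent month drives about half the value.
    """
    if n_windows < 1:
        raise DomainError("n_windows must be >= 1")
    glucose = baseline if isinstance(baseline, GlucoseValue) else GlucoseValue(float(baseline))
    base_mmoll = glucose.mmoll
    if base_mmoll <= 0:
        raise DomainError("baseline glucose must be strictly positive")
    delta = rel_perturbation * base_mmoll

    total_days = max(n_windows * window_days, params.lifespan_days)
    lead_days = total_days - n_windows * window_days
    window_s = window_days * SECONDS_PER_DAY

    def build(perturbed: int | None, sign: float) -> GlucoseTrajectory:
        durations: list[float] = []
        levels: list[float] = []
        if lead_days > 0:
            durations.append(lead_days * SECONDS_PER_DAY)
            levels.append(base_mmoll)
        for w in range(n_windows):  # earliest first
            durations.append(window_s)
            levels.append(base_mmoll + (sign * delta if w == perturbed else 0.0))
        return GlucoseTrajectory(tuple(durations), tuple(levels))

    sensitivities = []
    for w in range(n_windows):
        hi = cohort_hba1c(build(w, +1.0), params).hba1c_percent
        lo = cohort_hba1c(build(w, -1.0), params).hba1c_percent
        sensitivities.append((hi - lo) / (2.0 * delta))
    total = sum(sensitivities)
    if total <= 0 or not math.isfinite(total):
        raise NumericalError("degenerate sensitivity: all windows have zero effect")
    weights = tuple(s / total for s in sensitivities)
    return WeightScheme(f"implied{n_windows}x{window_days:g}d", weights)
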