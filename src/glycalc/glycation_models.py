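"""Closed-form relations between average glucose and glycated haemoglobin.

Three published maps from average glucose to HbA1c (NGSP percent) are
implemented, plus the weighted-average-glucose estimator that is this
package's reason to exist:

* the ADAG regression, ``eAG (mg/dl) = 28.7 * HbA1c(%) - 46.7``, and its
  inverse;
* the simulated-ADAG linear regression,
  ``HbA1c(%) = 0.0296 * eAG (mg/dl) + 2.419``;
* the erythrocyte-glycation kinetic closed form,
  ``HbA1c(%) = 91.5 * (1 - (1 - exp(-x)) / x) + 2.15`` with
  ``x = k * LS * eAG`` in self-consistent units (k in l/(mmol*s), the life
  span LS in seconds, eAG in mmol/l);
* the weighted average glucose ``wAG = sum(w_m * AGM_-m)`` over
  backward-looking monthly means, with the chronological weight presets
  20/30/50 (three months, earliest first), 10/15/25/50 (four months) and
  25/25/50.

A monthly profile and a weight scheme both carry explicit chronological
labels (``AGM-3``, ``AGM-2``, ``AGM-1``); pairing is validated by label so
an earliest-first profile can never be silently combined with a
most-recent-first weight vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULTS
from .errors import ConfigurationError, DomainError, UnitError

MGDL = "mg/dl"
MMOLL = "mmol/l"

#: grams per mole of glucose; 1 mmol/l of glucose is molar_mass/10 mg/dl.
GLUCOSE_MOLAR_MASS = DEFAULTS["glucose_molar_mass"]
MGDL_PER_MMOLL = GLUCOSE_MOLAR_MASS / 10.0

_UNIT_ALIASES = {
    "mg/dl": MGDL,
    "mgdl": MGDL,
    "mg/dL": MGDL,
    "mmol/l": MMOLL,
    "mmoll": MMOLL,
    "mmol/L": MMOLL,
}


def normalise_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip()]
    except (KeyError, AttributeError):
        raise UnitError(f"unknown glucose unit {unit!r}; expected mg/dl or mmol/l")


@dataclass(frozen=True)
class GlucoseValue:
    """A glucose concentration with its unit."""

    value: float
    unit: str = MGDL

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalise_unit(self.unit))
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(f"glucose must be finite and >= 0, got {self.value}")

    def to(self, target_unit: str) -> "GlucoseValue":
        return convert_glucose(self, target_unit)

    @property
    def mgdl(self) -> float:
        return self.value if self.unit == MGDL else self.value * MGDL_PER_MMOLL

    @property
    def mmoll(self) -> float:
        return self.value if self.unit == MMOLL else self.value / MGDL_PER_MMOLL


def convert_glucose(value: GlucoseValue, target_unit: str) -> GlucoseValue:
    """Express the same physical concentration in ``target_unit``.

    mg/dl -> mmol/l divides by 18.0156 (glucose molar mass 180.156 g/mol);
    the conversion is a fixed multiplicative factor and round-trips to
    machine precision.
    """
    target = normalise_unit(target_unit)
    if target == value.unit:
        return value
    if target == MMOLL:
        return GlucoseValue(value.value / MGDL_PER_MMOLL, MMOLL)
    return GlucoseValue(value.value * MGDL_PER_MMOLL, MGDL)


@dataclass(frozen=True)
class HbA1cValue:
    """Glycated haemoglobin on the NGSP percent scale."""

    percent: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.percent):
            raise DomainError(f"HbA1c must be finite, got {self.percent}")


@dataclass(frozen=True)
class LinearModel:
    """An invertible affine map between glucose (mg/dl) and HbA1c (%)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ConfigurationError("linear model slope must be non-zero")

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept

    def inverse(self, y: float) -> float:
        return (y - self.intercept) / self.slope


#: ADAG study regression: eAG in mg/dl as a function of HbA1c percent.
ADAG_MODEL = LinearModel(DEFAULTS["adag_slope"], DEFAULTS["adag_intercept"])

#: Regression of the simulated-ADAG population: HbA1c percent from eAG mg/dl.
SIMULATED_ADAG_MODEL = LinearModel(DEFAULTS["linear_slope"], DEFAULTS["linear_intercept"])


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the erythrocyte-glycation kinetic closed form.

    k is the haemoglobin glycation rate constant in l/(mmol*s); the
    life span is the erythrocyte circulating lifetime (cells are assumed
    uniformly age-distributed on [0, LS]). scale and offset map the mean
    glycated fraction onto the NGSP percent scale.
    """

    k: float = DEFAULTS["kinetic_k"]
    lifespan_days: float = DEFAULTS["lifespan_days"]
    scale_percent: float = DEFAULTS["kinetic_scale"]
    offset_percent: float = DEFAULTS["kinetic_offset"]

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError(f"rate constant k must be > 0, got {self.k}")
        if self.lifespan_days <= 0:
            raise ConfigurationError(
                f"life span must be > 0 days, got {self.lifespan_days}"
            )

    @property
    def lifespan_seconds(self) -> float:
        return self.lifespan_days * 86_400.0

    @classmethod
    def from_constants(cls, table: dict[str, float]) -> "KineticParams":
        return cls(
            k=table["kinetic_k"],
            lifespan_days=table["lifespan_days"],
            scale_percent=table["kinetic_scale"],
            offset_percent=table["kinetic_offset"],
        )


def _agm_labels(n: int) -> tuple[str, ...]:
    # earliest first: AGM-n ... AGM-1
    return tuple(f"AGM-{m}" for m in range(n, 0, -1))


@dataclass(frozen=True)
class MonthlyProfile:
    """Backward-looking monthly average glucose values, earliest first.

    ``months[0]`` is the earliest month (AGM-n) and ``months[-1]`` the most
    recent (AGM-1, the month immediately preceding the test).
    """

    months: tuple[GlucoseValue, ...]

    def __post_init__(self) -> None:
        months = tuple(
            m if isinstance(m, GlucoseValue) else GlucoseValue(float(m)) for m in self.months
        )
        object.__setattr__(self, "months", months)
        if len(months) < 1:
            raise ConfigurationError("a monthly profile needs at least one month")
        if any(m.value <= 0 for m in months):
            raise DomainError("all monthly averages must be strictly positive")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def labels(self) -> tuple[str, ...]:
        return _agm_labels(len(self.months))

    def values_mgdl(self) -> tuple[float, ...]:
        return tuple(m.mgdl for m in self.months)

    def mean_mgdl(self) -> float:
        vals = self.values_mgdl()
        return sum(vals) / len(vals)


@dataclass(frozen=True)
class WeightScheme:
    """Named chronological contribution weights, earliest month first."""

    name: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "weights", weights)
        if len(weights) < 1:
            raise ConfigurationError("a weight scheme needs at least one weight")
        if any(w < 0 for w in weights):
            raise ConfigurationError(f"weights must be non-negative: {weights}")
        total = sum(weights)
        # not silently renormalised: masking behaviour depends on exact normalisation
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"weights of scheme {self.name!r} sum to {total!r}, not 1"
            )

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def labels(self) -> tuple[str, ...]:
        return _agm_labels(len(self.weights))


def preset_schemes() -> list[WeightScheme]:
    """The built-in chronological weight presets (earliest first).

    ``default3`` is the 20/30/50 three-month scheme; ``fourmonth`` the
    10/15/25/50 variant; ``tahara3`` the 25/25/50 split in which the most
    recent month determines half of the HbA1c value.
    """
    return [
        WeightScheme("default3", (0.20, 0.30, 0.50)),
        WeightScheme("fourmonth", (0.10, 0.15, 0.25, 0.50)),
        WeightScheme("tahara3", (0.25, 0.25, 0.50)),
    ]


def get_scheme(name: str) -> WeightScheme:
    for scheme in preset_schemes():
        if scheme.name == name:
            return scheme
    known = ", ".join(s.name for s in preset_schemes())
    raise ConfigurationError(f"unknown weight scheme {name!r}; presets: {known}")


def eag_from_hba1c(hba1c: HbA1cValue | float, model: LinearModel = ADAG_MODEL) -> GlucoseValue:
    """Estimated average glucose (mg/dl) from HbA1c via the ADAG relation."""
    percent = hba1c.percent if isinstance(hba1c, HbA1cValue) else float(hba1c)
    eag = model(percent)
    if eag < 0:
        raise DomainError(
            f"HbA1c {percent}% maps below zero glucose (crossing at "
            f"{model.inverse(0.0):.4f}%)"
        )
    return GlucoseValue(eag, MGDL)


def hba1c_from_eag_adag(eag: GlucoseValue | float, model: LinearModel = ADAG_MODEL) -> HbA1cValue:
    """HbA1c from average glucose by inverting the ADAG relation."""
    mgdl = eag.mgdl if isinstance(eag, GlucoseValue) else float(eag)
    if mgdl < 0:
        raise DomainError(f"negative glucose {mgdl} mg/dl")
    return HbA1cValue(model.inverse(mgdl))


def hba1c_linear(
    eag: GlucoseValue | float, model: LinearModel = SIMULATED_ADAG_MODEL
) -> HbA1cValue:
    """HbA1c from the simulated-ADAG linear regression (eAG in mg/dl)."""
    mgdl = eag.mgdl if isinstance(eag, GlucoseValue) else float(eag)
    if mgdl < 0:
        raise DomainError(f"negative glucose {mgdl} mg/dl")
    return HbA1cValue(model(mgdl))


#: below this dimensionless exposure the closed form switches to its series.
SMALL_X_THRESHOLD = 1e-6


def _glycated_fraction_constant(x: float) -> float:
    """1 - (1 - exp(-x))/x, the life-span-averaged glycated fraction under
    constant glucose, continuous at x = 0 via the series x/2 - x^2/6."""
    if x < 0:
        raise DomainError(f"exposure x must be >= 0, got {x}")
    if x < SMALL_X_THRESHOLD:
        return x / 2.0 - x * x / 6.0
    return 1.0 - (1.0 - math.exp(-x)) / x


def hba1c_kinetic(
    eag: GlucoseValue | float, params: KineticParams = KineticParams()
) -> HbA1cValue:
    """HbA1c from the erythrocyte-glycation kinetic closed form.

    The exposure ``x = k * LS * eAG`` is formed in self-consistent units:
    k in l/(mmol*s) forces LS into seconds and eAG into mmol/l. A float
    ``eag`` is taken as mg/dl (the table unit) and converted.
    """
    glucose = eag if isinstance(eag, GlucoseValue) else GlucoseValue(float(eag), MGDL)
    x = params.k * params.lifespan_seconds * glucose.mmoll
    return HbA1cValue(
        params.scale_percent * _glycated_fraction_constant(x) + params.offset_percent
    )


def _check_pairing(profile: MonthlyProfile, scheme: WeightScheme) -> None:
    if profile.labels != scheme.labels:
        raise ConfigurationError(
            f"profile months {profile.labels} do not pair with scheme "
            f"{scheme.name!r} weights {scheme.labels}"
        )


def weighted_ag(profile: MonthlyProfile, scheme: WeightScheme) -> GlucoseValue:
    """Weighted average glucose: sum of w_m * AGM_-m, earliest-first pairing.

    The result is a convex combination, hence bounded by the smallest and
    largest monthly mean.
    """
    _check_pairing(profile, scheme)
    wag = sum(w * g for w, g in zip(scheme.weights, profile.values_mgdl()))
    return GlucoseValue(wag, MGDL)


def weighted_hba1c(
    profile: MonthlyProfile,
    scheme: WeightScheme,
    model: str = "linear",
    params: KineticParams = KineticParams(),
) -> HbA1cValue:
    """HbA1c of the weighted average glucose, via the linear or kinetic map."""
    wag = weighted_ag(profile, scheme)
    if model == "linear":
        return hba1c_linear(wag)
    if model == "kinetic":
        return hba1c_kinetic(wag, params)
    raise ConfigurationError(f"unknown model {model!r}; expected 'linear' or 'kinetic'")
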