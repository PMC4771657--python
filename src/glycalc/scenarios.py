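"""Built-in patient archetypes and the cross-model comparison table.

Three hypothetical individuals share the same plain 3-month mean glucose
(170 mg/dl) yet have very different histories:

* ISSC — steady-state control: 180, 170, 160 mg/dl (earliest first);
* IIC  — improving control: 250, 160, 100 mg/dl;
* IND  — newly diagnosed: 100, 100, 310 mg/dl.

An unweighted estimator gives all three the same HbA1c; the weighted
average glucose separates them. The comparison table reports, per profile,
the plain-mean eAG, the weighted wAG, and HbA1c under both the linear and
the kinetic map applied to each glucose summary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, DomainError
from .glycation_models import (
    HbA1cValue,
    KineticParams,
    MonthlyProfile,
    WeightScheme,
    get_scheme,
    hba1c_kinetic,
    hba1c_linear,
    weighted_ag,
)
from .rounding import display_mgdl, display_percent


@dataclass(frozen=True)
class ScenarioProfile:
    name: str
    description: str
    profile: MonthlyProfile


def builtin_profiles() -> list[ScenarioProfile]:
    """The three built-in archetypes (monthly values earliest first, mg/dl)."""
    return [
        ScenarioProfile(
            "ISSC",
            "individual with steady state control",
            MonthlyProfile((180, 170, 160)),
        ),
        ScenarioProfile(
            "IIC",
            "individual with improving control",
            MonthlyProfile((250, 160, 100)),
        ),
        ScenarioProfile(
            "IND",
            "individual newly diagnosed",
            MonthlyProfile((100, 100, 310)),
        ),
    ]


def get_profile(name: str) -> ScenarioProfile:
    for scenario in builtin_profiles():
        if scenario.name == name.upper():
            return scenario
    known = ", ".join(s.name for s in builtin_profiles())
    raise ConfigurationError(f"unknown profile {name!r}; built-ins: {known}")


@dataclass(frozen=True)
class ComparisonRow:
    name: str
    agm_values: tuple[float, ...]
    mean_eag: float
    wag: float
    hba1c_linear_mean: float
    hba1c_linear_weighted: float
    hba1c_kinetic_mean: float
    hba1c_kinetic_weighted: float


_COLUMNS = [
    "mean_eag",
    "wag",
    "hba1c_linear_mean",
    "hba1c_linear_weighted",
    "hba1c_kinetic_mean",
    "hba1c_kinetic_weighted",
]


@dataclass(frozen=True)
class ComparisonTable:
    rows: tuple[ComparisonRow, ...]

    def to_dataframe(self, display: bool = False) -> pd.DataFrame:
        """Full-precision frame, or the display rendering (glucose to
        integers, percent to 2 decimals, half away from zero)."""
        records = []
        for row in self.rows:
            rec = {
                "name": row.name,
                **{f"agm_{i}": v for i, v in zip(range(-len(row.agm_values), 0), row.agm_values)},
                **{col: getattr(row, col) for col in _COLUMNS},
            }
            records.append(rec)
        frame = pd.DataFrame.from_records(records)
        if display:
            for col in ("mean_eag", "wag"):
                frame[col] = frame[col].map(display_mgdl)
            for col in _COLUMNS[2:]:
                frame[col] = frame[col].map(display_percent)
        return frame

    def to_csv(self, display: bool = False) -> str:
        return self.to_dataframe(display=display).to_csv(index=False)

    def to_text(self) -> str:
        """Aligned human-readable rendering at display rounding."""
        frame = self.to_dataframe(display=True)
        for col in ("mean_eag", "wag"):
            frame[col] = frame[col].map(lambda v: f"{v:.0f}")
        for col in _COLUMNS[2:]:
            frame[col] = frame[col].map(lambda v: f"{v:.2f}")
        buf = io.StringIO()
        frame.to_string(buf, index=False)
        return buf.getvalue()


def build_comparison_table(
    profiles: list[ScenarioProfile] | None = None,
    scheme: WeightScheme | None = None,
    params: KineticParams = KineticParams(),
) -> ComparisonTable:
    """One row per profile: plain-mean and weighted glucose, and the four
    HbA1c estimates (linear/kinetic x mean/weighted), all full precision."""
    if profiles is None:
        profiles = builtin_profiles()
    if scheme is None:
        scheme = get_scheme("default3")
    if not profiles:
        raise ConfigurationError("no profiles to compare")
    rows = []
    for scenario in profiles:
        profile = scenario.profile
        mean_eag = profile.mean_mgdl()
        wag = weighted_ag(profile, scheme).mgdl
        rows.append(
            ComparisonRow(
                name=scenario.name,
                agm_values=profile.values_mgdl(),
                mean_eag=mean_eag,
                wag=wag,
                hba1c_linear_mean=hba1c_linear(mean_eag).percent,
                hba1c_linear_weighted=hba1c_linear(wag).percent,
                hba1c_kinetic_mean=hba1c_kinetic(mean_eag, params).percent,
                hba1c_kinetic_weighted=hba1c_kinetic(wag, params).percent,
            )
        )
    return ComparisonTable(tuple(rows))


def relative_variation(a: HbA1cValue | float, b: HbA1cValue | float) -> float:
    """Relative difference (a - b)/a as a fraction.

    By convention ``a`` is the larger (kinetic-weighted) and ``b`` the
    smaller (linear-weighted) estimate, so the kinetic value is the
    denominator; with the built-in profiles this gives ~3% per profile.
    """
    av = a.percent if isinstance(a, HbA1cValue) else float(a)
    bv = b.percent if isinstance(b, HbA1cValue) else float(b)
    if av == 0:
        raise DomainError("zero denominator in relative variation")
    return (av - bv) / av
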