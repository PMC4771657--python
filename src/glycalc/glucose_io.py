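"""Reading timestamped glucose CSVs and aggregating to monthly means.

Input format: RFC-4180 CSV, UTF-8, header ``timestamp,value[,unit]``,
ISO-8601 timestamps. The canonical internal unit is mg/dl; a per-row unit
column (mg/dl or mmol/l) is converted on load.

A "month" is a backward-looking 30-day window from the test date, not a
calendar month: window m covers [test_date - m*window_days,
test_date - (m-1)*window_days), half-open, so each record falls in exactly
one window and a record at exactly the test instant belongs to none (it is
warned about, not used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    CoverageError,
    FormatError,
    ValidationError,
)
from .glycation_models import (
    GlucoseValue,
    HbA1cValue,
    KineticParams,
    MonthlyProfile,
    WeightScheme,
    get_scheme,
    hba1c_kinetic,
    hba1c_linear,
    normalise_unit,
    weighted_ag,
    MGDL,
)
from .rounding import display_mgdl, display_percent

logger = logging.getLogger("glycalc")


@dataclass(frozen=True)
class GlucoseRecord:
    timestamp: datetime
    value: GlucoseValue


@dataclass(frozen=True)
class ReadingSeries:
    """Timestamped readings, sorted ascending, in one common unit (mg/dl)."""

    records: tuple[GlucoseRecord, ...]
    unit: str = MGDL

    def __len__(self) -> int:
        return len(self.records)


def read_glucose_csv(path: str | Path, unit_override: str | None = None) -> ReadingSeries:
    """Load a readings CSV into a sorted, mg/dl-normalised series.

    ``unit_override`` forces a unit for every row (useful for headerless
    meters exporting mmol/l without a unit column); otherwise the optional
    ``unit`` column applies per row and the default is mg/dl.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: not parseable as CSV: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("timestamp", "value"):
        if col not in frame.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} (found {list(frame.columns)})"
            )

    timestamps = pd.to_datetime(frame["timestamp"], format="ISO8601", errors="coerce")
    bad_ts = frame.index[timestamps.isna()]
    if len(bad_ts):
        rows = ", ".join(str(i + 2) for i in bad_ts[:5])  # +2: header + 1-based
        raise ValidationError(f"{path}: unparseable ISO-8601 timestamp at line(s) {rows}")

    values = pd.to_numeric(frame["value"], errors="coerce")
    bad_val = frame.index[values.isna() | (values <= 0)]
    if len(bad_val):
        rows = ", ".join(str(i + 2) for i in bad_val[:5])
        raise ValidationError(f"{path}: non-positive or non-numeric value at line(s) {rows}")

    if unit_override is not None:
        units = [normalise_unit(unit_override)] * len(frame)
    elif "unit" in frame.columns:
        units = [normalise_unit(u) if isinstance(u, str) and u.strip() else MGDL
                 for u in frame["unit"]]
    else:
        units = [MGDL] * len(frame)

    records = [
        GlucoseRecord(ts.to_pydatetime(), GlucoseValue(float(v), u).to(MGDL))
        for ts, v, u in zip(timestamps, values, units)
    ]
    records.sort(key=lambda r: r.timestamp)
    return ReadingSeries(tuple(records), MGDL)


def write_glucose_csv(series: ReadingSeries, path: str | Path) -> None:
    """Write the standard CSV dialect (header timestamp,value,unit)."""
    frame = pd.DataFrame(
        {
            "timestamp": [r.timestamp.isoformat() for r in series.records],
            "value": [repr(r.value.value) for r in series.records],
            "unit": [r.value.unit for r in series.records],
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def monthly_averages(
    series: ReadingSeries,
    test_date: date | datetime,
    n_months: int = 3,
    window_days: int = 30,
    min_readings: int = 1,
    with_counts: bool = False,
) -> MonthlyProfile | tuple[MonthlyProfile, tuple[int, ...]]:
    """Arithmetic mean glucose per backward-looking window, earliest first.

    Window m (m = 1 most recent) is [test - m*window_days, test - (m-1)*window_days),
    half-open so the partition has no gaps or overlaps; the most recent
    window excludes the test instant itself.
    """
    if n_months < 1 or window_days < 1:
        raise ConfigurationError("n_months and window_days must be >= 1")
    test_dt = (
        test_date
        if isinstance(test_date, datetime)
        else datetime(test_date.year, test_date.month, test_date.day)
    )
    if series.records and all(r.timestamp < test_dt - timedelta(days=n_months * window_days)
                              for r in series.records):
        raise CoverageError(
            f"all {len(series)} readings predate the {n_months * window_days}-day "
            f"window before {test_dt.date()}"
        )
    at_test = sum(1 for r in series.records if r.timestamp == test_dt)
    if at_test:
        logger.warning(
            "%d reading(s) at exactly the test instant %s fall in no window",
            at_test, test_dt.isoformat(),
        )

    means: list[float] = []
    counts: list[int] = []
    for m in range(n_months, 0, -1):  # earliest window first
        start = test_dt - timedelta(days=m * window_days)
        end = test_dt - timedelta(days=(m - 1) * window_days)
        window = [r.value.mgdl for r in series.records if start <= r.timestamp < end]
        if len(window) < min_readings:
            raise CoverageError(
                f"window AGM-{m} [{start.date()} .. {end.date()}) has "
                f"{len(window)} reading(s); need >= {min_readings}"
            )
        means.append(sum(window) / len(window))
        counts.append(len(window))
    profile = MonthlyProfile(tuple(GlucoseValue(v, MGDL) for v in means))
    if with_counts:
        return profile, tuple(counts)
    return profile


@dataclass(frozen=True)
class EstimateConfig:
    """Inputs to one end-to-end estimation run."""

    input_path: str | None = None
    profile_name: str | None = None
    test_date: date | None = None
    n_months: int = 3
    window_days: int = 30
    scheme: WeightScheme | None = None
    model: str = "both"  # linear | kinetic | both
    unit_override: str | None = None
    min_readings: int = 1
    params: KineticParams = field(default_factory=KineticParams)


@dataclass(frozen=True)
class EstimateReport:
    """Profile, weighted glucose and the four HbA1c estimates.

    Raw fields are full precision; the text/CSV renderings add the display
    rounding (integers for mg/dl, 2 decimals for percent).
    """

    profile: MonthlyProfile
    scheme: WeightScheme
    reading_counts: tuple[int, ...] | None
    mean_eag_raw: float
    wag_raw: float
    hba1c_linear_mean_raw: float
    hba1c_linear_weighted_raw: float
    hba1c_kinetic_mean_raw: float
    hba1c_kinetic_weighted_raw: float

    def to_dataframe(self) -> pd.DataFrame:
        row = {
            **{f"agm_{lbl.lower().replace('agm', '')}": v
               for lbl, v in zip(self.profile.labels, self.profile.values_mgdl())},
            "mean_eag": display_mgdl(self.mean_eag_raw),
            "wag": display_mgdl(self.wag_raw),
            "hba1c_linear_mean": display_percent(self.hba1c_linear_mean_raw),
            "hba1c_linear_weighted": display_percent(self.hba1c_linear_weighted_raw),
            "hba1c_kinetic_mean": display_percent(self.hba1c_kinetic_mean_raw),
            "hba1c_kinetic_weighted": display_percent(self.hba1c_kinetic_weighted_raw),
            "mean_eag_raw": self.mean_eag_raw,
            "wag_raw": self.wag_raw,
            "hba1c_linear_mean_raw": self.hba1c_linear_mean_raw,
            "hba1c_linear_weighted_raw": self.hba1c_linear_weighted_raw,
            "hba1c_kinetic_mean_raw": self.hba1c_kinetic_mean_raw,
            "hba1c_kinetic_weighted_raw": self.hba1c_kinetic_weighted_raw,
        }
        return pd.DataFrame.from_records([row])

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False)

    def to_text(self) -> str:
        lines = [f"scheme: {self.scheme.name} {self.scheme.weights}"]
        for i, (lbl, v) in enumerate(zip(self.profile.labels, self.profile.values_mgdl())):
            count = f"  ({self.reading_counts[i]} readings)" if self.reading_counts else ""
            lines.append(f"{lbl}: {v:g} mg/dl{count}")
        lines += [
            f"mean eAG: {display_mgdl(self.mean_eag_raw):.0f} mg/dl",
            f"wAG:      {display_mgdl(self.wag_raw):.0f} mg/dl",
            f"HbA1c linear  (mean eAG): {display_percent(self.hba1c_linear_mean_raw):.2f} %",
            f"HbA1c linear  (wAG):      {display_percent(self.hba1c_linear_weighted_raw):.2f} %",
            f"HbA1c kinetic (mean eAG): {display_percent(self.hba1c_kinetic_mean_raw):.2f} %",
            f"HbA1c kinetic (wAG):      {display_percent(self.hba1c_kinetic_weighted_raw):.2f} %",
        ]
        return "\n".join(lines)


def run_estimate(config: EstimateConfig) -> EstimateReport:
    """CSV or built-in profile -> monthly profile -> wAG -> HbA1c estimates."""
    if (config.input_path is None) == (config.profile_name is None):
        raise ConfigurationError("provide exactly one of input_path or profile_name")
    if config.model not in ("linear", "kinetic", "both"):
        raise ConfigurationError(f"unknown model {config.model!r}")

    if config.input_path is not None:
        if config.test_date is None:
            raise ConfigurationError("test_date is required with an input file")
        series = read_glucose_csv(config.input_path, config.unit_override)
        profile, counts = monthly_averages(
            series, config.test_date, config.n_months, config.window_days,
            config.min_readings, with_counts=True,
        )
    else:
        from .scenarios import get_profile

        profile = get_profile(config.profile_name).profile
        counts = None

    scheme = config.scheme if config.scheme is not None else get_scheme("default3")
    wag = weighted_ag(profile, scheme)
    mean_eag = profile.mean_mgdl()
    return EstimateReport(
        profile=profile,
        scheme=scheme,
        reading_counts=counts,
        mean_eag_raw=mean_eag,
        wag_raw=wag.mgdl,
        hba1c_linear_mean_raw=hba1c_linear(mean_eag).percent,
        hba1c_linear_weighted_raw=hba1c_linear(wag).percent,
        hba1c_kinetic_mean_raw=hba1c_kinetic(mean_eag, config.params).percent,
        hba1c_kinetic_weighted_raw=hba1c_kinetic(wag, config.params).percent,
    )
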