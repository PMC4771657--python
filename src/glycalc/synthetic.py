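"""Synthetic daily self-monitored glucose series with known monthly means.

Emulates a patient taking ``readings_per_day`` finger-stick measurements a
day, where each backward-looking window has a specified target mean and
readings scatter around it with independent Gaussian noise. Timestamps are
deterministic (fixed clock times, evenly spaced through the day); only the
values are random, driven by one explicitly-seeded generator, so the same
seed always yields a byte-identical CSV.

Deliberately not modelled: meal spikes, dawn phenomenon, hypoglycaemic
episodes, day-to-day autocorrelation — this is a fixture generator for the
aggregation pipeline, not a glycaemic simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .errors import ConfigurationError
from .glycation_models import MGDL, GlucoseValue, MonthlyProfile
from .glucose_io import GlucoseRecord, ReadingSeries

#: readings below this are clipped up (glucose meters do not report <= 0)
FLOOR_MGDL = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Target window means plus sampling noise configuration."""

    profile: MonthlyProfile
    readings_per_day: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    window_days: int = 30

    def __post_init__(self) -> None:
        if self.readings_per_day < 1:
            raise ConfigurationError("readings_per_day must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.window_days < 1:
            raise ConfigurationError("window_days must be >= 1")


def generate_readings(spec: SimulationSpec, test_date: date | datetime) -> ReadingSeries:
    """Daily readings for every window of the profile, ending at test_date.

    For window m (earliest first in the profile) each of its ``window_days``
    days carries ``readings_per_day`` records at the window's target mean
    plus N(0, noise_sd) noise, truncated below at 1 mg/dl. Reading j of K
    per day sits at clock time (j + 0.5) * 24/K hours, strictly before the
    test instant.
    """
    test_dt = (
        test_date
        if isinstance(test_date, datetime)
        else datetime(test_date.year, test_date.month, test_date.day)
    )
    rng = np.random.default_rng(spec.seed)
    n = len(spec.profile)
    k = spec.readings_per_day
    records: list[GlucoseRecord] = []
    for idx, month in enumerate(spec.profile.months):
        m = n - idx  # chronological window index, m = 1 most recent
        start = test_dt - timedelta(days=m * spec.window_days)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.window_days * k) if spec.noise_sd else np.zeros(spec.window_days * k)
        for day in range(spec.window_days):
            for j in range(k):
                ts = start + timedelta(days=day, hours=(j + 0.5) * 24.0 / k)
                value = max(month.mgdl + float(noise[day * k + j]), FLOOR_MGDL)
                records.append(GlucoseRecord(ts, GlucoseValue(value, MGDL)))
    records.sort(key=lambda r: r.timestamp)
    return ReadingSeries(tuple(records), MGDL)
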