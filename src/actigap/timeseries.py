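"""Epoch- and hour-resolution activity series with explicit missing-data semantics.

The raw substrate is a week of wrist-acceleration vector-magnitude values, one
per 30-s epoch, in milli-g. Missing epochs ("absent": the sensor recorded
nothing) are carried as NaN and are distinct from genuine zeros (the sensor on
a table records real zeros). Records are midnight-aligned and cover an integer
number of days so that hour-of-day labels are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ABSENT",
    "FormatError",
    "EpochSeries",
    "HourlySeries",
    "read_epoch_csv",
    "write_epoch_csv",
    "hourly_average",
]

#: Distinguished marker for an epoch with no recorded value.
ABSENT = float("nan")

SECONDS_PER_DAY = 86_400
CSV_HEADER = "timestamp,acceleration_mg"


class FormatError(ValueError):
    """Raised when an epoch CSV violates the expected dialect or timing grid."""


def is_absent(x) -> np.ndarray | bool:
    """True where a value is the ABSENT marker."""
    return np.isnan(x)


@dataclass(frozen=True)
class EpochSeries:
    """Uniformly spaced acceleration epochs covering whole days.

    Parameters
    ----------
    start_instant
        Local date-time of the first epoch; must be midnight.
    epoch_seconds
        Epoch length in seconds (30 throughout this study).
    values
        Non-negative acceleration magnitudes in milli-g; NaN marks ABSENT.
    """

    start_instant: datetime
    epoch_seconds: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.epoch_seconds <= 0 or SECONDS_PER_DAY % self.epoch_seconds:
            raise ValueError(f"epoch_seconds must divide a day, got {self.epoch_seconds}")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        epd = self.epochs_per_day
        if vals.size % epd:
            raise ValueError(
                f"record length {vals.size} is not a whole number of days "
                f"({epd} epochs/day)"
            )
        with np.errstate(invalid="ignore"):
            if np.any(vals < 0):
                raise ValueError("acceleration values must be non-negative")
        if (self.start_instant.hour, self.start_instant.minute,
                self.start_instant.second, self.start_instant.microsecond) != (0, 0, 0, 0):
            raise ValueError("start_instant must be local midnight")

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_seconds

    @property
    def n_days(self) -> int:
        return self.values.size // self.epochs_per_day

    @property
    def n_epochs(self) -> int:
        return self.values.size

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_instant, periods=self.n_epochs, freq=f"{self.epoch_seconds}s"
        )

    def with_values(self, values: np.ndarray) -> "EpochSeries":
        """Copy of this series with replaced values (same grid)."""
        return EpochSeries(self.start_instant, self.epoch_seconds, values)


@dataclass(frozen=True)
class HourlySeries:
    """Hourly mean activity with hour-of-day labels.

    ``values[i]`` is the mean over hour i's available epochs (NaN if none);
    ``hour_of_day[i]`` cycles 1..hours_per_day starting at 1 (midnight-1 a.m.
    is hour 1).
    """

    values: np.ndarray = field(repr=False)
    hour_of_day: np.ndarray = field(repr=False)
    hours_per_day: int = 24

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        hod = np.asarray(self.hour_of_day, dtype=int)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "hour_of_day", hod)
        if vals.shape != hod.shape or vals.ndim != 1:
            raise ValueError("values and hour_of_day must be equal-length 1-D arrays")
        if np.any((hod < 1) | (hod > self.hours_per_day)):
            raise ValueError("hour_of_day labels must lie in 1..hours_per_day")

    @property
    def n_hours(self) -> int:
        return self.values.size


def read_epoch_csv(path) -> EpochSeries:
    """Read an epoch CSV (``timestamp,acceleration_mg``; empty cell = ABSENT).

    Timestamps must be ISO-8601, in time order, uniformly spaced, and start at
    midnight; the record must cover whole days.
    """
    df = pd.read_csv(path, header=0, float_precision="round_trip")
    if list(df.columns) != CSV_HEADER.split(","):
        raise FormatError(f"{path}: expected header '{CSV_HEADER}', got {list(df.columns)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamps: {exc}") from None
    if len(ts) < 2:
        raise FormatError(f"{path}: need at least two rows")
    deltas = np.diff(ts.to_numpy().astype("datetime64[s]").astype(np.int64))
    if deltas.min() != deltas.max() or deltas[0] <= 0:
        raise FormatError(f"{path}: timestamps are not uniformly increasing")
    epoch_seconds = int(deltas[0])
    raw = df["acceleration_mg"]
    coerced = pd.to_numeric(raw, errors="coerce")
    if (raw.notna() & coerced.isna()).any():
        raise FormatError(f"{path}: non-numeric acceleration values")
    return EpochSeries(ts.iloc[0].to_pydatetime(), epoch_seconds, coerced.to_numpy(float))


def write_epoch_csv(series: EpochSeries, path) -> Path:
    """Write the canonical epoch CSV dialect; ABSENT becomes an empty field."""
    path = Path(path)
    ts = series.timestamps().strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w", newline="") as fh:
        fh.write(CSV_HEADER + "\n")
        for t, v in zip(ts, series.values):
            fh.write(f"{t},{'' if np.isnan(v) else repr(float(v))}\n")
    return path


def hourly_average(series: EpochSeries) -> HourlySeries:
    """Bin an epoch series to hourly means.

    Each clock hour's value is the arithmetic mean of its available (non-ABSENT)
    epochs; genuine zeros count as data. An hour with no available epoch is
    ABSENT. Hour-of-day labels follow clock time: the midnight-to-1 a.m. bin of
    every day is hour 1.
    """
    per_hour = 3600 // series.epoch_seconds
    mat = series.values.reshape(-1, per_hour)
    counts = np.sum(~np.isnan(mat), axis=1)
    sums = np.nansum(mat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_hours = means.size
    hod = (np.arange(n_hours) % 24) + 1
    return HourlySeries(values=means, hour_of_day=hod, hours_per_day=24)
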