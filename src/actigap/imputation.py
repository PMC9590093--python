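"""Statistical gap filling at epoch resolution.

Three imputers replace the epochs inside known missing-data bouts:

* ``linear`` — a straight line through the last valid epoch before and the
  first valid epoch after the gap.
* ``mean_tod`` — for each gap epoch, the mean over other days' values at the
  same clock time (time of day).
* ``median_tod`` — as above with the median; less sensitive to outlier days.

The bout list, not the stored value, defines the gap, so the imputers behave
identically whether the gap was masked with zeros or with NaNs. Epochs inside
any bout are never used as donors: under the zero phenotype they hold
known-spurious zeros, and under the NaN phenotype they hold nothing.
These methods aim to stabilize downstream rhythm metrics, not to reconstruct
the true time series.
"""

from __future__ import annotations

import logging

import numpy as np

from .timeseries import EpochSeries

__all__ = [
    "LINEAR",
    "MEAN_TOD",
    "MEDIAN_TOD",
    "METHODS",
    "impute",
    "impute_linear",
    "impute_mean_tod",
    "impute_median_tod",
]

logger = logging.getLogger(__name__)

LINEAR = "linear"
MEAN_TOD = "mean_tod"
MEDIAN_TOD = "median_tod"
METHODS = (LINEAR, MEAN_TOD, MEDIAN_TOD)


def _bout_slices(series: EpochSeries, bouts) -> list[slice]:
    per_min = 60 // series.epoch_seconds
    slices = []
    for start, dur in bouts:
        sl = slice(start * per_min, (start + dur) * per_min)
        if sl.stop > series.n_epochs:
            raise ValueError(f"bout ({start}, {dur}) extends past the record end")
        slices.append(sl)
    return slices


def _gap_index_mask(series: EpochSeries, bouts) -> np.ndarray:
    mask = np.zeros(series.n_epochs, dtype=bool)
    for sl in _bout_slices(series, bouts):
        mask[sl] = True
    return mask


def impute(series: EpochSeries, bouts, method: str) -> EpochSeries:
    """Fill the epochs inside ``bouts`` with the named method.

    ``bouts`` is a list of (start_offset_minutes, duration_minutes) pairs;
    epochs outside the bouts are returned bitwise unchanged.
    """
    if method not in METHODS:
        raise ValueError(f"unknown imputation method {method!r}; expected one of {METHODS}")
    values = series.values.copy()
    if method == LINEAR:
        for sl in _bout_slices(series, bouts):
            values[sl] = impute_linear(series, sl)
    else:
        fills = _tod_fill(series, bouts, use_median=(method == MEDIAN_TOD))
        gap = _gap_index_mask(series, bouts)
        values[gap] = fills[gap]
    return series.with_values(values)


def impute_linear(series: EpochSeries, bout: slice) -> np.ndarray:
    """Line through the flanking epochs, evaluated at each gap epoch.

    A gap touching the record boundary has no flank on that side; the
    available flank is held constant across the gap (a logged fallback, since
    the interpolation line is undefined there).
    """
    n = series.n_epochs
    i0, i1 = bout.start - 1, bout.stop  # flank indices
    gap_idx = np.arange(bout.start, bout.stop)
    left = series.values[i0] if i0 >= 0 else np.nan
    right = series.values[i1] if i1 < n else np.nan
    if np.isnan(left) and np.isnan(right):
        raise ValueError("linear imputation needs at least one valid flanking epoch")
    if np.isnan(left) or np.isnan(right):
        flank = right if np.isnan(left) else left
        logger.warning(
            "gap [%d, %d) touches the record boundary; holding flank value %g",
            bout.start, bout.stop, flank,
        )
        return np.full(gap_idx.size, float(flank))
    slope = (right - left) / (i1 - i0)
    return left + slope * (gap_idx - i0)


def _tod_fill(series: EpochSeries, bouts, use_median: bool) -> np.ndarray:
    """Per-epoch time-of-day fill values (full-length array, NaN off-gap).

    Donors for a clock time are that time's epochs on all days that are
    neither inside a bout nor ABSENT. Raises when some gap epoch's clock time
    has no donor day at all.
    """
    epd = series.epochs_per_day
    mat = series.values.reshape(series.n_days, epd).astype(float).copy()
    gap2d = _gap_index_mask(series, bouts).reshape(series.n_days, epd)
    mat[gap2d] = np.nan  # bout epochs are never donors
    needed = gap2d.any(axis=0)
    donors_per_col = np.sum(~np.isnan(mat[:, needed]), axis=0)
    if np.any(donors_per_col == 0):
        bad = np.flatnonzero(needed)[donors_per_col == 0][0]
        raise ValueError(
            f"no donor day for time-of-day epoch {int(bad)} "
            f"({int(bad) * series.epoch_seconds // 3600:02d}:"
            f"{int(bad) * series.epoch_seconds % 3600 // 60:02d})"
        )
    stat = np.nanmedian if use_median else np.nanmean
    col_fill = np.full(epd, np.nan)
    col_fill[needed] = stat(mat[:, needed], axis=0)
    return np.tile(col_fill, series.n_days)


def impute_mean_tod(series: EpochSeries, bout) -> np.ndarray:
    """Mean-over-other-days fill values for one bout (given in minutes)."""
    fills = _tod_fill(series, [bout], use_median=False)
    return fills[_gap_index_mask(series, [bout])]


def impute_median_tod(series: EpochSeries, bout) -> np.ndarray:
    """Median-over-other-days fill values for one bout (given in minutes).

    With an even donor count the median is the mean of the two central order
    statistics.
    """
    fills = _tod_fill(series, [bout], use_median=True)
    return fills[_gap_index_mask(series, [bout])]
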