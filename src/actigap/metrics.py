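"""Nonparametric rest-activity rhythm metrics: intradaily variability (IV)
and interdaily stability (IS).

Both metrics are ratios of sums of squares over hourly mean activity X_i,
i = 1..n, with grand mean X̄:

    IV = n * Σ_{i=2..n} (X_i - X_{i-1})^2 / [(n-1) * Σ_i (X_i - X̄)^2]
    IS = n * Σ_{h=1..p} (X̄_h - X̄)^2   / [p     * Σ_i (X_i - X̄)^2]

where p is the number of hour-of-day bins (24) and X̄_h the mean over days of
hour-of-day h. IV measures rhythm fragmentation (hour-to-hour change relative
to overall variance); IS measures day-to-day regularity (fraction of variance
explained by the average 24-h profile). For complete whole-day data
0 <= IS <= 1; IV is non-negative (a strictly alternating series reaches 4, so
the often-quoted upper value 2 is descriptive of real data, not a bound).

ABSENT (NaN) hours are handled by available-case deletion with count
adjustment: means and the denominator run over the valid hours (n_used), the
IV numerator over consecutive pairs that are both valid (m pairs), and IS
hour-of-day bins with no valid day are dropped (p_used). Degenerate
denominators yield UNDEFINED (NaN), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .timeseries import EpochSeries, HourlySeries, hourly_average

__all__ = [
    "UNDEFINED",
    "NonparametricMetrics",
    "compute_iv",
    "compute_is",
    "compute_metrics",
    "affected_term_fraction",
    "iv_affected_pair_count",
]

#: Marker for a metric whose denominator vanished or that has no valid terms.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class NonparametricMetrics:
    """IV/IS for one record, with the term counts actually used."""

    IV: float
    IS: float
    n_hours_used: int
    n_diff_terms_used: int
    n_hour_of_day_bins_used: int


def compute_iv(hourly: HourlySeries) -> NonparametricMetrics:
    """Intradaily variability of an hourly series (IS left UNDEFINED).

    Requires at least two valid hours. Returns UNDEFINED IV when no two
    consecutive valid hours exist or the hourly variance is zero.
    """
    x = hourly.values
    valid = ~np.isnan(x)
    n_used = int(valid.sum())
    if n_used < 2:
        raise ValueError(f"need >= 2 valid hours to compute IV, got {n_used}")
    xbar = x[valid].mean()
    denom_ss = float(((x[valid] - xbar) ** 2).sum())
    pair_ok = valid[1:] & valid[:-1]
    m = int(pair_ok.sum())
    num_ss = float(((x[1:] - x[:-1])[pair_ok] ** 2).sum())
    if denom_ss == 0.0 or m == 0:
        iv = UNDEFINED
    else:
        iv = n_used * num_ss / (m * denom_ss)
    return NonparametricMetrics(iv, UNDEFINED, n_used, m, 0)


def compute_is(hourly: HourlySeries) -> NonparametricMetrics:
    """Interdaily stability of an hourly series (IV left UNDEFINED).

    Requires the series to span at least two days. Hour-of-day bins with no
    valid hour are dropped from the numerator (p_used tracks survivors).
    """
    x = hourly.values
    p = hourly.hours_per_day
    if x.size < 2 * p:
        raise ValueError("need at least 2 days of hourly data to compute IS")
    valid = ~np.isnan(x)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValueError("no valid hours")
    xbar = x[valid].mean()
    denom_ss = float(((x[valid] - xbar) ** 2).sum())
    hod = hourly.hour_of_day
    bin_means = []
    for h in range(1, p + 1):
        sel = valid & (hod == h)
        if sel.any():
            bin_means.append(x[sel].mean())
    p_used = len(bin_means)
    num_ss = float(((np.asarray(bin_means) - xbar) ** 2).sum())
    if denom_ss == 0.0 or p_used == 0:
        is_ = UNDEFINED
    else:
        is_ = n_used * num_ss / (p_used * denom_ss)
    return NonparametricMetrics(UNDEFINED, is_, n_used, 0, p_used)


def compute_metrics(series: EpochSeries) -> NonparametricMetrics:
    """Hourly-bin an epoch series, then compute both IV and IS."""
    hourly = hourly_average(series)
    iv_part = compute_iv(hourly)
    is_part = compute_is(hourly)
    return NonparametricMetrics(
        IV=iv_part.IV,
        IS=is_part.IS,
        n_hours_used=iv_part.n_hours_used,
        n_diff_terms_used=iv_part.n_diff_terms_used,
        n_hour_of_day_bins_used=is_part.n_hour_of_day_bins_used,
    )


def iv_affected_pair_count(record_hours: int, gap_hours: int) -> int:
    """Exact number of consecutive-difference terms touched by an interior gap.

    A contiguous interior gap of g hours enters g+1 of the n-1 difference
    terms (each gap hour's two flanking differences, shared between
    neighbours), capped at n-1.
    """
    _check_gap_args(record_hours, gap_hours)
    return min(gap_hours + 1, record_hours - 1)


def affected_term_fraction(metric: str, record_hours: int, gap_hours: int) -> Fraction:
    """Fraction of metric terms touched by a contiguous gap, by convention.

    For IV the convention counts one affected difference term per gap hour:
    gap_hours / (record_hours - 1); the strict touched-pair count is available
    from :func:`iv_affected_pair_count`. For IS the fraction is the number of
    gap-touched hour-of-day bins out of 24: min(gap_hours, 24) / 24.

    Returns an exact :class:`fractions.Fraction` (e.g. 1/167 for a one-hour
    gap in a week of data for IV, 1/24 for IS).
    """
    _check_gap_args(record_hours, gap_hours)
    metric = metric.upper()
    if metric == "IV":
        return Fraction(gap_hours, record_hours - 1)
    if metric == "IS":
        return Fraction(min(gap_hours, 24), 24)
    raise ValueError(f"metric must be 'IV' or 'IS', got {metric!r}")


def _check_gap_args(record_hours: int, gap_hours: int) -> None:
    if record_hours < 2:
        raise ValueError("record_hours must be >= 2")
    if not 1 <= gap_hours < record_hours:
        raise ValueError("gap_hours must satisfy 1 <= gap_hours < record_hours")
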