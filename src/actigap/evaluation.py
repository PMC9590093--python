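"""Cohort-level agreement analysis.

For each masking condition, IV/IS from the adulterated record (masked, or
masked-then-imputed) are compared against the unadulterated record's values
via Bland-Altman statistics: the mean difference (bias), the 1.96 x SD limits
of agreement, and the OLS slope of difference on average (proportional bias).
Per-condition statistics are assembled into heatmap grids indexed by the mask
grid coordinates (start hour x duration, or start hour x separation), one grid
per metric, statistic, condition, and start day. A long-format CSV of all cells
is the canonical artifact; rendering is optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imputation
from .masking import ABSENT_PHENOTYPE, MaskSpec, ZERO, apply_mask
from .metrics import NonparametricMetrics, compute_metrics
from .timeseries import EpochSeries

__all__ = [
    "BlandAltmanSummary",
    "HeatmapGrid",
    "BoutStats",
    "bland_altman",
    "run_condition",
    "build_heatmaps",
    "heatmaps_to_frame",
    "bout_statistics",
    "STATISTICS",
    "CONDITIONS",
]

STATISTICS = ("mean_diff", "sd_diff", "slope")
CONDITIONS = ("masked-zero", "masked-absent", "linear", "mean_tod", "median_tod")


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Agreement summary for one condition across a cohort.

    ``loa_half_width`` is 1.96 x sd_diff (the half-width of the limits of
    agreement); slope/intercept come from OLS of difference on average.
    """

    mean_diff: float
    sd_diff: float
    loa_half_width: float
    slope: float
    intercept: float
    n_pairs: int


@dataclass(frozen=True)
class HeatmapGrid:
    """2-D array of one Bland-Altman statistic over a mask grid.

    ``cells[y, x]`` holds the statistic for the mask at ``y_axis[y]`` (duration
    or separation, hours) and ``x_axis[x]`` (start hour); NaN marks grid cells
    whose mask did not fit inside the record.
    """

    statistic: str
    metric: str
    condition: str
    start_day: int
    x_axis: tuple
    y_axis: tuple
    y_kind: str  # "duration_h" or "separation_h"
    cells: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.cells.shape != (len(self.y_axis), len(self.x_axis)):
            raise ValueError("cells shape must be |y_axis| x |x_axis|")


@dataclass(frozen=True)
class BoutStats:
    """Descriptive statistics of per-record missing-data bouts."""

    n_records: int
    bout_count_histogram: dict
    harmonic_mean_first_bout_min: float
    harmonic_mean_second_bout_min: float


def bland_altman(true_values, test_values) -> BlandAltmanSummary:
    """Bland-Altman summary of test vs. true metric values across a cohort.

    Pairs with an UNDEFINED (NaN) member are dropped; ``n_pairs`` counts the
    survivors. The SD uses the n-1 sample estimator. With fewer than two
    surviving pairs, or a degenerate regression, the slope is UNDEFINED.
    """
    t = np.asarray(true_values, dtype=float)
    s = np.asarray(test_values, dtype=float)
    if t.shape != s.shape:
        raise ValueError("true and test lists must be aligned and equal length")
    keep = ~(np.isnan(t) | np.isnan(s))
    t, s = t[keep], s[keep]
    n = t.size
    if n == 0:
        raise ValueError("no surviving pairs")
    diff = s - t
    avg = (s + t) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1)) if n >= 2 else float("nan")
    slope = intercept = float("nan")
    if n >= 2:
        var_avg = float(((avg - avg.mean()) ** 2).sum())
        var_diff = float(((diff - mean_diff) ** 2).sum())
        if var_avg > 0.0:
            slope = float(((avg - avg.mean()) * (diff - mean_diff)).sum() / var_avg)
            intercept = mean_diff - slope * float(avg.mean())
        elif var_diff == 0.0:
            # all averages identical and all differences identical: flat fit
            slope, intercept = 0.0, mean_diff
    return BlandAltmanSummary(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_half_width=1.96 * sd_diff,
        slope=slope,
        intercept=intercept,
        n_pairs=int(n),
    )


def run_condition(
    cohort, mask: MaskSpec, method: str = "none", true_metrics=None
):
    """Per-participant (true, test) metric pairs for one masking condition.

    ``method`` is ``"none"`` (metrics of the masked record), an imputation
    method name (metrics of the masked-then-imputed record), or a callable
    ``(series, bouts) -> EpochSeries`` test hook. ``true_metrics`` lets callers
    reuse precomputed unadulterated metrics.

    Returns a list of (NonparametricMetrics, NonparametricMetrics) pairs.
    """
    if true_metrics is None:
        true_metrics = [compute_metrics(rec) for rec in cohort]
    pairs = []
    for rec, truth in zip(cohort, true_metrics):
        if method == "none":
            test_rec = apply_mask(rec, mask)
        elif callable(method):
            test_rec = method(rec, mask.bouts)
        else:
            # imputers read only epochs outside the bouts, so imputing the
            # pristine record over the bout list equals mask-then-impute
            test_rec = imputation.impute(rec, mask.bouts, method)
        pairs.append((truth, compute_metrics(test_rec)))
    return pairs


def _mask_y(mask: MaskSpec):
    label = mask.label
    if "duration_h" in label:
        return "duration_h", label["duration_h"]
    if "separation_h" in label:
        return "separation_h", label["separation_h"]
    raise ValueError("mask label lacks duration_h/separation_h grid coordinate")


def build_heatmaps(
    cohort, grid, methods=("none", *imputation.METHODS), x_axis=None, y_axis=None
) -> list[HeatmapGrid]:
    """Assemble Bland-Altman heatmaps over a mask grid.

    ``grid`` is a list of labelled MaskSpecs (from the masking module);
    ``methods`` selects conditions: ``"none"`` yields one masked-<phenotype>
    condition per phenotype present in the grid, and each imputation method
    yields one condition shared across phenotypes (the imputers see only the
    bout list). Explicit ``x_axis``/``y_axis`` preserve grid cells that were
    omitted at generation time as NaN cells; by default the axes are inferred
    from the masks present.
    """
    if not grid:
        raise ValueError("empty mask grid")
    y_kind, _ = _mask_y(grid[0])
    xs = sorted({m.label["start_hour"] for m in grid}) if x_axis is None else list(x_axis)
    ys = sorted({_mask_y(m)[1] for m in grid}) if y_axis is None else list(y_axis)
    days = sorted({m.label["start_day"] for m in grid})
    x_pos = {v: i for i, v in enumerate(xs)}
    y_pos = {v: i for i, v in enumerate(ys)}

    true_metrics = [compute_metrics(rec) for rec in cohort]
    true_by_metric = {
        "IV": np.array([m.IV for m in true_metrics]),
        "IS": np.array([m.IS for m in true_metrics]),
    }

    # accumulate per (metric, statistic, condition, day) grids
    grids: dict[tuple, np.ndarray] = {}

    def cell_store(metric, stat, condition, day):
        key = (metric, stat, condition, day)
        if key not in grids:
            grids[key] = np.full((len(ys), len(xs)), np.nan)
        return grids[key]

    impute_methods = [m for m in methods if m != "none"]
    mask_conditions = "none" in methods

    # geometry key -> imputed metrics cache (phenotype-independent)
    seen_geometry: dict[tuple, dict] = {}

    for mask in grid:
        day = mask.label["start_day"]
        yi = y_pos[_mask_y(mask)[1]]
        xi = x_pos[mask.label["start_hour"]]
        if mask_conditions:
            pairs = run_condition(cohort, mask, "none", true_metrics)
            _fill(grids, cell_store, pairs, f"masked-{mask.phenotype}", day, yi, xi,
                  true_by_metric)
        if impute_methods:
            geom = (mask.bouts, day, yi, xi)
            if geom not in seen_geometry:
                seen_geometry[geom] = {}
                for method in impute_methods:
                    pairs = run_condition(cohort, mask, method, true_metrics)
                    name = method if isinstance(method, str) else getattr(
                        method, "__name__", "custom")
                    _fill(grids, cell_store, pairs, name, day, yi, xi, true_by_metric)

    out = []
    for (metric, stat, condition, day), cells in sorted(grids.items()):
        out.append(
            HeatmapGrid(
                statistic=stat, metric=metric, condition=condition, start_day=day,
                x_axis=tuple(xs), y_axis=tuple(ys), y_kind=y_kind, cells=cells,
            )
        )
    return out


def _fill(grids, cell_store, pairs, condition, day, yi, xi, true_by_metric):
    for metric in ("IV", "IS"):
        truth = true_by_metric[metric]
        test = np.array([getattr(p[1], metric) for p in pairs])
        keep = ~(np.isnan(truth) | np.isnan(test))
        if keep.sum() == 0:
            continue
        summ = bland_altman(truth, test)
        for stat in STATISTICS:
            cell_store(metric, stat, condition, day)[yi, xi] = getattr(summ, stat)


def heatmaps_to_frame(heatmaps) -> pd.DataFrame:
    """Long-format table of heatmap cells (the canonical serialization)."""
    rows = []
    for hm in heatmaps:
        for yi, yv in enumerate(hm.y_axis):
            for xi, xv in enumerate(hm.x_axis):
                rows.append(
                    {
                        "start_day": hm.start_day,
                        "start_hour": xv,
                        "duration_or_separation": yv,
                        "metric": hm.metric,
                        "statistic": hm.statistic,
                        "condition": hm.condition,
                        "value": hm.cells[yi, xi],
                    }
                )
    return pd.DataFrame(rows)


def render_heatmap(hm: HeatmapGrid, path) -> None:
    """Optional basic rendering of one grid to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(hm.cells, aspect="auto", origin="lower", cmap="RdYlGn_r")
    ax.set_xticks(range(len(hm.x_axis)), hm.x_axis)
    ax.set_yticks(range(len(hm.y_axis)), hm.y_axis)
    ax.set_xlabel("start hour of day")
    ax.set_ylabel(hm.y_kind.replace("_h", " (h)"))
    ax.set_title(f"{hm.metric} {hm.statistic} — {hm.condition}, day {hm.start_day}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def bout_statistics(bout_lists) -> BoutStats:
    """Summarize per-record missing-bout durations.

    ``bout_lists`` holds one ordered list of bout durations (minutes) per
    record. Reports the histogram of bouts per record and the harmonic means
    H = k / sum(1/d_j) of first-bout and second-bout durations (the latter over
    records with at least two bouts).
    """
    bout_lists = [list(b) for b in bout_lists]
    hist: dict[int, int] = {}
    firsts, seconds = [], []
    for bouts in bout_lists:
        bouts = list(bouts)
        if any(d <= 0 for d in bouts):
            raise ValueError("bout durations must be positive")
        hist[len(bouts)] = hist.get(len(bouts), 0) + 1
        if len(bouts) >= 1:
            firsts.append(bouts[0])
        if len(bouts) >= 2:
            seconds.append(bouts[1])

    def hmean(xs):
        if not xs:
            return float("nan")
        return len(xs) / math.fsum(1.0 / x for x in xs)

    return BoutStats(
        n_records=len(bout_lists),
        bout_count_histogram=hist,
        harmonic_mean_first_bout_min=hmean(firsts),
        harmonic_mean_second_bout_min=hmean(seconds),
    )
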