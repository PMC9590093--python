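import numpy as np
import pytest

from actigap import SyntheticConfig, generate_cohort
from actigap.evaluation import build_heatmaps, heatmaps_to_frame
from actigap.masking import (
    DEFAULT_DURATIONS_H,
    DEFAULT_START_HOURS,
    single_gap_grid,
)


@pytest.fixture(scope="session")
def cohort20():
    """Default-configuration synthetic cohort used by the simulation studies."""
    return generate_cohort(SyntheticConfig(seed=7), 20)


@pytest.fixture(scope="session")
def small_cohort():
    """Three records for cheap structural tests."""
    return generate_cohort(SyntheticConfig(seed=11), 3)


@pytest.fixture(scope="session")
def day2_frame(cohort20):
    """Long-format heatmap cells for the full single-gap grid on start day 2,
    both phenotypes, all imputation methods."""
    grid = single_gap_grid(start_days=[2])
    hms = build_heatmaps(
        cohort20, grid,
        methods=("none", "linear", "mean_tod", "median_tod"),
        x_axis=DEFAULT_START_HOURS, y_axis=DEFAULT_DURATIONS_H,
    )
    return heatmaps_to_frame(hms)


def mean_diff_cells(frame, condition, metric):
    sub = frame[
        (frame.statistic == "mean_diff")
        & (frame.condition == condition)
        & (frame.metric == metric)
    ]
    return sub


@pytest.fixture(scope="session")
def mean_diff():
    return mean_diff_cells
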