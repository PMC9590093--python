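import math

import numpy as np
import pytest

from actigap.evaluation import (
    bland_altman,
    bout_statistics,
    build_heatmaps,
    heatmaps_to_frame,
    run_condition,
)
from actigap.masking import (
    DEFAULT_DURATIONS_H,
    DEFAULT_START_HOURS,
    MaskSpec,
    single_gap_grid,
)


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_slope(self):
        s = bland_altman([0.3, 0.9, 0.5], [0.3, 0.9, 0.5])
        assert (s.mean_diff, s.sd_diff, s.slope) == (0.0, 0.0, 0.0)
        assert s.loa_half_width == 0.0
        assert s.n_pairs == 3

    def test_identity_on_constant_values(self):
        s = bland_altman([0.5, 0.5], [0.5, 0.5])
        assert (s.mean_diff, s.sd_diff, s.slope) == (0.0, 0.0, 0.0)

    def test_constant_differences(self):
        s = bland_altman([0.5, 0.6], [0.6, 0.7])
        assert s.mean_diff == pytest.approx(0.1)
        assert s.sd_diff == pytest.approx(0.0, abs=1e-15)
        assert s.slope == pytest.approx(0.0, abs=1e-12)

    def test_two_point_slope_closed_form(self):
        # diffs [0, 0.2] over avgs [0.2, 0.9] -> slope 0.2/0.7
        s = bland_altman([0.2, 0.8], [0.2, 1.0])
        assert s.slope == pytest.approx(0.2 / 0.7)
        assert s.loa_half_width == pytest.approx(1.96 * s.sd_diff)

    def test_swapping_roles_negates_bias(self):
        a, b = [0.2, 0.8, 0.4], [0.3, 0.7, 0.6]
        fwd = bland_altman(a, b)
        rev = bland_altman(b, a)
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.slope == pytest.approx(-fwd.slope)

    def test_undefined_pairs_dropped(self):
        s = bland_altman([0.2, float("nan"), 0.8], [0.25, 0.5, 0.9])
        assert s.n_pairs == 2

    def test_single_pair_has_undefined_slope(self):
        s = bland_altman([0.5], [0.7])
        assert s.n_pairs == 1 and math.isnan(s.slope)

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="no surviving pairs"):
            bland_altman([float("nan")], [0.5])


class TestRunCondition:
    def test_empty_mask_gives_identical_pairs(self, small_cohort):
        mask = MaskSpec("zero", (), {"start_day": 1, "start_hour": 0, "duration_h": 0})
        pairs = run_condition(small_cohort, mask, "none")
        for truth, test in pairs:
            assert test.IV == pytest.approx(truth.IV, rel=1e-12)
            assert test.IS == pytest.approx(truth.IS, rel=1e-12)

    def test_oracle_imputer_hook_recovers_truth(self, small_cohort):
        mask = MaskSpec("zero", ((600, 300),), {"start_day": 1, "start_hour": 10,
                                                "duration_h": 5})
        pairs = run_condition(small_cohort, mask, method=lambda rec, bouts: rec)
        for truth, test in pairs:
            assert test.IV == truth.IV and test.IS == truth.IS

    def test_long_midday_zero_gap_lowers_is(self, cohort20):
        # 23-h gap starting 10:00 on day 3
        start = (2 * 24 + 10) * 60
        mask = MaskSpec("zero", ((start, 23 * 60),),
                        {"start_day": 3, "start_hour": 10, "duration_h": 23})
        pairs = run_condition(cohort20, mask, "none")
        deltas = [test.IS - truth.IS for truth, test in pairs]
        assert np.mean(deltas) < 0


class TestBuildHeatmaps:
    def test_single_day_single_phenotype_shapes(self, small_cohort):
        grid = single_gap_grid(start_days=[1], phenotypes=("zero",))
        hms = build_heatmaps(small_cohort, grid, methods=("none",))
        # 1 condition x 2 metrics x 3 statistics
        assert len(hms) == 6
        for hm in hms:
            assert hm.cells.shape == (12, 12)
            assert hm.condition == "masked-zero"
            assert not np.isnan(hm.cells).any()

    def test_all_methods_emit_five_conditions(self, day2_frame):
        conds = set(day2_frame.condition)
        assert conds == {"masked-zero", "masked-absent", "linear", "mean_tod",
                         "median_tod"}
        assert set(day2_frame.metric) == {"IV", "IS"}
        assert set(day2_frame.statistic) == {"mean_diff", "sd_diff", "slope"}
        # 5 conditions x 2 metrics x 3 statistics x 144 cells
        assert len(day2_frame) == 5 * 2 * 3 * 144

    def test_identical_cohort_empty_mask_grid_is_zero(self, small_cohort):
        cohort = [small_cohort[0]] * 4
        grid = [MaskSpec("zero", ((0, 60),), {"start_day": 1, "start_hour": 0,
                                              "duration_h": 1})]
        hms = build_heatmaps(cohort, grid, methods=(lambda r, b: r,))
        # oracle imputer on identical records: zero bias everywhere
        for hm in hms:
            if hm.statistic == "mean_diff":
                assert np.allclose(hm.cells, 0.0)

    def test_omitted_day7_cells_are_empty(self, small_cohort):
        grid = single_gap_grid(start_days=[7], phenotypes=("zero",))
        hms = build_heatmaps(
            small_cohort, grid, methods=("none",),
            x_axis=DEFAULT_START_HOURS, y_axis=DEFAULT_DURATIONS_H,
        )
        hm = hms[0]
        yi = hm.y_axis.index(23)
        xi = hm.x_axis.index(22)
        assert np.isnan(hm.cells[yi, xi])       # did not fit the record
        assert not np.isnan(hm.cells[0, 0])     # 1-h gap at midnight fits

    def test_long_format_roundtrip(self, small_cohort):
        grid = single_gap_grid(start_days=[1], durations_h=[1, 3], start_hours=[0, 2],
                               phenotypes=("zero",))
        hms = build_heatmaps(small_cohort, grid, methods=("none",))
        frame = heatmaps_to_frame(hms)
        assert len(frame) == 6 * 4
        assert set(frame.columns) == {
            "start_day", "start_hour", "duration_or_separation", "metric",
            "statistic", "condition", "value",
        }


class TestBoutStatistics:
    def test_two_value_harmonic_mean(self):
        stats = bout_statistics([[100], [150]])
        assert stats.harmonic_mean_first_bout_min == pytest.approx(120.0)
        assert stats.bout_count_histogram == {1: 2}

    def test_constant_durations(self):
        stats = bout_statistics([[113, 136]] * 5)
        assert stats.harmonic_mean_first_bout_min == pytest.approx(113.0)
        assert stats.harmonic_mean_second_bout_min == pytest.approx(136.0)
        assert stats.bout_count_histogram == {2: 5}

    def test_three_value_harmonic_mean(self):
        stats = bout_statistics([[60], [120], [240]])
        assert stats.harmonic_mean_first_bout_min == pytest.approx(3 / (1 / 60 + 1 / 120 + 1 / 240))
        assert stats.harmonic_mean_first_bout_min == pytest.approx(102.857142857, rel=1e-9)

    def test_harmonic_below_arithmetic(self):
        firsts = [[d] for d in (30, 60, 200, 500)]
        stats = bout_statistics(firsts)
        assert stats.harmonic_mean_first_bout_min <= np.mean([30, 60, 200, 500])

    def test_zero_duration_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            bout_statistics([[0, 10]])
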