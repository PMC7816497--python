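"""Conditional survival, the CS matrix/series and standardized differences."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rptcs import (
    classify_band,
    conditional_matrix,
    conditional_survival,
    cs3_series,
    d_series,
    generate_cohort,
    km_curve,
    standardized_difference,
    stratified_cs3,
    survival_at,
)
from rptcs.conditional import ConditionalUndefinedError
from rptcs.synthetic import PiecewiseRate

from conftest import make_cohort, uncensored_exponential_config


class TestConditionalSurvival:
    def test_y_zero_gives_one_hundred(self, five_records):
        curve = km_curve(five_records, "OS")
        assert conditional_survival(curve, 0.25, 0) == pytest.approx(100.0)

    def test_x_zero_reduces_to_actual_survival(self):
        cohort = make_cohort([6, 12, 18, 24, 30], [True, True, False, True, False])
        curve = km_curve(cohort, "OS")
        assert conditional_survival(curve, 0, 2) == pytest.approx(
            100.0 * survival_at(curve, 24).survival
        )

    def test_ratio_on_raw_values_is_scale_invariant(self):
        assert conditional_survival((0.898, 0.655), 1, 3) == pytest.approx(
            conditional_survival((89.8, 65.5), 1, 3)
        )

    def test_zero_denominator_is_undefined(self, five_records):
        curve = km_curve(five_records, "OS")  # S = 0 at month 7
        with pytest.raises(ConditionalUndefinedError):
            conditional_survival(curve, 7 / 12, 1 / 12)

    def test_horizon_beyond_followup_errors(self, five_records):
        curve = km_curve(five_records, "OS")
        with pytest.raises(ValueError):
            conditional_survival(curve, 0, 2)

    def test_telescoping_identity_on_synthetic_curve(self, default_cohort):
        curve = km_curve(default_cohort, "OS")
        for x in range(0, 4):
            for y1 in range(0, 4):
                for y2 in range(0, 4):
                    if 12 * (x + y1 + y2) > curve.max_time:
                        continue
                    lhs = conditional_survival(curve, x, y1 + y2)
                    rhs = (
                        conditional_survival(curve, x, y1)
                        * conditional_survival(curve, x + y1, y2)
                        / 100.0
                    )
                    assert lhs == pytest.approx(rhs, abs=1e-12)


class TestCS3Series:
    def test_baseline_equals_actual_three_year_survival(self, default_cohort):
        curve = km_curve(default_cohort, "CSS")
        series = cs3_series(curve, x_max=5)
        assert series.cs[0] == pytest.approx(100.0 * survival_at(curve, 36).survival)
        assert series.cs[0] == pytest.approx(series.actual[0])

    def test_flat_under_constant_hazard(self):
        cohort = generate_cohort(uncensored_exponential_config(0.012, 40_000, 71))
        series = cs3_series(km_curve(cohort, "OS"), x_max=5)
        assert series.x_years == list(range(6))
        for value in series.cs[1:]:
            assert value == pytest.approx(series.cs[0], abs=1.5)

    def test_increasing_under_decreasing_hazard(self):
        cfg = uncensored_exponential_config(0.03, 40_000, 72).replace(
            baseline_hazard_cancer=PiecewiseRate(
                (0.0, 24.0, 48.0, 72.0), (0.030, 0.012, 0.005, 0.002)
            )
        )
        series = cs3_series(km_curve(generate_cohort(cfg), "OS"), x_max=5)
        assert all(np.diff(series.cs) > 0)

    def test_truncates_with_warning_when_followup_short(self):
        cohort = make_cohort([10, 20, 30, 40], [True, False, True, False])
        curve = km_curve(cohort, "OS")  # 40 months of follow-up
        with pytest.warns(UserWarning, match="truncated"):
            series = cs3_series(curve, x_max=5)
        assert series.x_years == [0]


@pytest.fixture(scope="module")
def curve():
    cohort = generate_cohort(uncensored_exponential_config(0.01, 3000, 55))
    return km_curve(cohort, "OS")


class TestConditionalMatrix:
    def test_diagonal_is_exactly_100(self, curve):
        matrix = conditional_matrix(curve, 5)
        for total in matrix.table.index:
            assert matrix.table.loc[total, total] == 100.0

    def test_column_zero_reproduces_actual_survival(self, curve):
        matrix = conditional_matrix(curve, 5)
        for total in matrix.table.index:
            assert matrix.table.loc[total, 0] == pytest.approx(
                100.0 * survival_at(curve, 12 * total).survival
            )

    def test_cells_above_diagonal_are_masked(self, curve):
        matrix = conditional_matrix(curve, 4)
        for total in matrix.table.index:
            for x in matrix.table.columns:
                assert pd.isna(matrix.table.loc[total, x]) == (x > total)

    def test_rows_nondecreasing_left_to_right(self, curve):
        matrix = conditional_matrix(curve, 6)
        for _, row in matrix.table.iterrows():
            vals = row.dropna().to_numpy()
            assert (np.diff(vals) >= -1e-9).all()

    def test_telescoping_between_cells(self, curve):
        matrix = conditional_matrix(curve, 5)
        t = matrix.table
        assert t.loc[5, 1] == pytest.approx(
            t.loc[4, 1] * t.loc[5, 4] / 100.0, abs=1e-9
        )

    def test_no_event_cohort_is_100_everywhere(self):
        cohort = make_cohort([80] * 6, [False] * 6)
        matrix = conditional_matrix(km_curve(cohort, "OS"), 5)
        assert np.nanmin(matrix.table.to_numpy()) == 100.0

    def test_survivor_subset_oracle(self):
        # with no censoring, CS(y|x) equals the empirical survival of the
        # survivors past 12x months
        cohort = generate_cohort(
            uncensored_exponential_config(0.02, 2000, 77)
        )
        curve = km_curve(cohort, "OS")
        durations = cohort["followup_months"].to_numpy()
        for x, y in [(1, 2), (2, 3), (3, 1)]:
            survivors = durations > 12 * x
            expected = 100.0 * np.sum(durations > 12 * (x + y)) / np.sum(survivors)
            assert conditional_survival(curve, x, y) == pytest.approx(expected, abs=1e-9)


class TestStandardizedDifference:
    def test_equal_rates_give_zero_and_band_none(self):
        sd = standardized_difference(0.4, 0.4, 0.4)
        assert sd.d == 0.0
        assert sd.band == "none"

    def test_sign_follows_first_listed_group(self):
        assert standardized_difference(0.8, 0.6, 0.7).d > 0
        assert standardized_difference(0.6, 0.8, 0.7).d < 0

    @pytest.mark.parametrize(
        "d,band",
        [
            (0.05, "none"),
            (-0.05, "none"),
            (0.1, "small"),
            (0.29, "small"),
            (-0.3, "moderate"),
            (0.49, "moderate"),
            (0.5, "significant"),
            (-1.2, "significant"),
        ],
    )
    def test_band_cut_points(self, d, band):
        assert classify_band(d) == band

    def test_degenerate_pooled_rate_is_an_error(self):
        with pytest.raises(ValueError):
            standardized_difference(0.5, 0.4, 0.0)
        with pytest.raises(ValueError):
            standardized_difference(0.5, 0.4, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        p2=st.floats(0.0, 1.0),
        p1=st.floats(0.0, 1.0),
        p=st.floats(0.01, 0.99),
    )
    def test_antisymmetry_and_band_total_order(self, p2, p1, p):
        sd = standardized_difference(p2, p1, p)
        swapped = standardized_difference(p1, p2, p)
        assert sd.d == pytest.approx(-swapped.d, abs=1e-12)
        assert sd.band == swapped.band  # band depends on |d| only
        assert sd.band in ("none", "small", "moderate", "significant")

    @settings(derandomize=True, max_examples=200)
    @given(
        s=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3).map(sorted)
    )
    def test_telescoping_holds_for_any_monotone_survival_values(self, s):
        s_low, s_mid, s_high = s  # S(x+y1+y2) <= S(x+y1) <= S(x)
        lhs = conditional_survival((s_high, s_low), 1, 2)
        rhs = (
            conditional_survival((s_high, s_mid), 1, 1)
            * conditional_survival((s_mid, s_low), 2, 1)
            / 100.0
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestStratifiedAndDSeries:
    def test_single_level_factor_matches_pooled(self):
        cohort = generate_cohort(uncensored_exponential_config(0.01, 800, 81))
        cohort["fnclcc_grade"] = "II"
        pooled = cs3_series(km_curve(cohort, "OS"), 4)
        strat = stratified_cs3(cohort, "fnclcc_grade", "OS", 4)
        assert list(strat) == ["II"]
        np.testing.assert_allclose(strat["II"].cs, pooled.cs)

    def test_empty_level_is_an_error(self):
        cohort = generate_cohort(uncensored_exponential_config(0.01, 300, 82))
        with pytest.raises(ValueError, match="frankengrade|IV"):
            stratified_cs3(cohort, "fnclcc_grade", "OS", 3, levels=["I", "IV"])

    def test_identical_generating_laws_give_null_d(self):
        cohort = generate_cohort(uncensored_exponential_config(0.01, 40_000, 83))
        pooled = cs3_series(km_curve(cohort, "OS"), 4)
        strat = stratified_cs3(cohort, "sex", "OS", 4)
        diffs = d_series(strat, pooled, [("male", "female")])[("male", "female")]
        for _, sd in diffs:
            assert abs(sd.d) < 0.1

    def test_planted_grade_effect_widens_low_grade_gap(self):
        cfg = uncensored_exponential_config(0.006, 40_000, 84).replace(
            baseline_hazard_cancer=PiecewiseRate(
                (0.0, 24.0, 48.0), (0.020, 0.008, 0.003)
            ),
            log_hr_cancer={"fnclcc_grade": {"III": 1.2}},
        )
        cohort = generate_cohort(cfg)
        strat = stratified_cs3(cohort, "fnclcc_grade", "OS", 5)
        rise_iii = strat["III"].cs[-1] - strat["III"].cs[0]
        rise_i = strat["I"].cs[-1] - strat["I"].cs[0]
        assert rise_iii > rise_i

    def test_identical_series_give_all_zero_d(self):
        cohort = generate_cohort(uncensored_exponential_config(0.01, 500, 85))
        pooled = cs3_series(km_curve(cohort, "OS"), 3)
        strat = {"a": pooled, "b": pooled}
        diffs = d_series(strat, pooled, [("a", "b")])[("a", "b")]
        assert all(sd.d == 0.0 for _, sd in diffs)

    def test_missing_level_raises_keyerror(self):
        cohort = generate_cohort(uncensored_exponential_config(0.01, 500, 86))
        pooled = cs3_series(km_curve(cohort, "OS"), 3)
        strat = stratified_cs3(cohort, "sex", "OS", 3)
        with pytest.raises(KeyError):
            d_series(strat, pooled, [("male", "nonexistent")])
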