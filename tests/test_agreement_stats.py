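"""Yield, bias, precision, bootstrap, Bland-Altman, RMS, Spearman, RCV."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from echoagree.agreement_stats import (
    SQRT2,
    DifferenceSet,
    InsufficientDataError,
    bland_altman_loa,
    bootstrap_ci,
    compute_yield,
    paired_differences,
    percentile_precision,
    reference_change_value,
    rms_error,
    robust_bias,
    spearman_correlation,
    summarize_agreement,
)
from echoagree.core_io import MeasurementTable


def _ds(diffs, base=10.0):
    """DifferenceSet whose nominal differences equal `diffs`."""
    d = np.asarray(diffs, dtype=float)
    ref = np.full(len(d), base)
    return DifferenceSet(
        parameter="TRV",
        ref_reader="CL1",
        comp_reader="DL",
        subjects=np.arange(len(d)).astype(str),
        ref=ref,
        comp=ref + d,
    )


def _presence_table(n_ref, n_comp, n_common, n_total=None):
    """Table realizing given reference/comparator read counts and overlap."""
    if n_total is None:
        n_total = n_ref + n_comp - n_common  # size of the read union
    records = []
    for i in range(n_total):
        sid = f"S{i:04d}"
        if i < n_ref:
            records.append({"subject_id": sid, "parameter": "TRV", "reader": "CL1", "value": 2.5})
        in_comp = i < n_common or n_ref <= i < n_ref + (n_comp - n_common)
        if in_comp:
            records.append({"subject_id": sid, "parameter": "TRV", "reader": "DL", "value": 2.6})
    return MeasurementTable.from_records(records)


class TestYield:
    @pytest.mark.parametrize(
        "n_ref,n_comp,n_common,expected",
        [(396, 403, 370, 93.4), (422, 357, 341, 80.8), (316, 319, 302, 95.6)],
    )
    def test_relative_yield_from_counts(self, n_ref, n_comp, n_common, expected):
        table = _presence_table(n_ref, n_comp, n_common)
        y = compute_yield(table, "TRV", "CL1", "DL")
        assert (y.n_ref, y.n_comp, y.n_common) == (n_ref, n_comp, n_common)
        assert round(y.relative_yield_pct, 1) == expected

    def test_complete_overlap_is_100_percent(self):
        table = _presence_table(50, 50, 50, n_total=50)
        assert compute_yield(table, "TRV", "CL1", "DL").relative_yield_pct == 100.0

    def test_zero_reference_reads_is_an_error(self):
        table = _presence_table(0, 10, 0, n_total=20)
        with pytest.raises(InsufficientDataError):
            compute_yield(table, "TRV", "CL1", "DL")


class TestPairedDifferences:
    def test_hand_arithmetic_with_pair_mean_denominator(self):
        table = MeasurementTable.from_records(
            [
                {"subject_id": "S1", "parameter": "TRV", "reader": "CL1", "value": 4.0},
                {"subject_id": "S1", "parameter": "TRV", "reader": "DL", "value": 4.2},
            ]
        )
        ds = paired_differences(table, "TRV", "CL1", "DL")
        assert ds.nominal_diffs[0] == pytest.approx(0.2)
        assert ds.relative_diffs[0] == pytest.approx(100 * 0.2 / 4.1)
        assert ds.range_axis[0] == pytest.approx(4.1)

    def test_sign_convention_negative_when_comparator_lower(self):
        ds = DifferenceSet("TRV", "CL1", "DL", ["S1"], [2.0], [1.8])
        assert ds.nominal_diffs[0] == pytest.approx(-0.2)

    def test_identical_reads_give_zero_differences(self, small_table):
        ds = paired_differences(small_table, "TRV", "CL1", "CL1")
        assert np.all(ds.nominal_diffs == 0.0)
        assert np.all(ds.relative_diffs == 0.0)

    def test_no_common_reads_is_an_error(self):
        table = _presence_table(5, 0, 0, n_total=10)
        with pytest.raises(InsufficientDataError):
            paired_differences(table, "TRV", "CL1", "DL")

    def test_nonpositive_pair_mean_excluded_from_relative_scale(self):
        ds = DifferenceSet("TRV", "CL1", "DL", ["a", "b"], [1.0, -3.0], [1.5, 1.0])
        assert ds.n_excluded_relative == 1
        assert len(ds.relative_diffs) == 1


class TestRobustBias:
    @pytest.mark.parametrize(
        "diffs,expected",
        [([-1, 0, 1], 0.0), ([1, 2, 3, 4], 2.5), ([1, 2, 3, 4, 100], 3.0)],
    )
    def test_median_with_interpolation_and_outlier_resistance(self, diffs, expected):
        assert robust_bias(_ds(diffs)) == pytest.approx(expected)


class TestPercentilePrecision:
    def test_constant_differences_have_zero_dispersion(self):
        assert percentile_precision(_ds([0.7] * 10), scaled=False) == 0.0

    def test_integer_grid_with_linear_interpolation_convention(self):
        # 0..100: the k-th of n points sits at (k-1)/(n-1), so P16=16, P84=84.
        ds = _ds(np.arange(101.0))
        assert percentile_precision(ds, scaled=False) == pytest.approx(34.0)
        assert percentile_precision(ds, scaled=True) == pytest.approx(34.0 / SQRT2)

    def test_standard_normal_scaled_precision_near_normal_quantile(self):
        # (P84 - P16)/2 estimates Phi^-1(0.84) ~ 0.9945; / sqrt(2) ~ 0.7032.
        d = np.random.default_rng(123).normal(size=10**6)
        got = percentile_precision(_ds(d), scaled=True)
        assert got == pytest.approx(sps.norm.ppf(0.84) / SQRT2, abs=0.01)

    def test_scaling_identity_exact(self):
        d = np.random.default_rng(7).normal(size=501)
        ds = _ds(d)
        assert percentile_precision(ds, scaled=True) * SQRT2 == pytest.approx(
            percentile_precision(ds, scaled=False), rel=1e-12
        )

    def test_single_difference_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            percentile_precision(_ds([1.0]))


class TestBootstrap:
    def test_constant_data_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci("bias", _ds([2.0] * 20), B=100, seed=0)
        assert lo == hi == 2.0

    def test_same_seed_reproduces_interval(self):
        ds = _ds(np.random.default_rng(5).normal(size=60))
        assert bootstrap_ci("bias", ds, B=500, seed=11) == bootstrap_ci(
            "bias", ds, B=500, seed=11
        )

    def test_precision_statistic_never_fails_on_degenerate_resamples(self):
        lo, hi = bootstrap_ci("precision", _ds([1.0, 1.0, 2.0]), B=200, seed=1)
        assert lo >= 0.0 and hi >= lo

    def test_interval_brackets_the_point_estimate(self):
        ds = _ds(np.random.default_rng(9).normal(1.0, 1.0, 300))
        lo, hi = bootstrap_ci("bias", ds, B=1000, seed=3)
        assert lo <= robust_bias(ds) <= hi


class TestBlandAltmanAndRMS:
    def test_two_point_limits_of_agreement(self):
        mean, lo, hi = bland_altman_loa(_ds([-1.0, 1.0]))
        assert mean == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * math.sqrt(2.0))
        assert lo == pytest.approx(-hi)

    def test_constant_differences_collapse_loa(self):
        assert bland_altman_loa(_ds([0.5] * 5)) == pytest.approx((0.5, 0.5, 0.5))

    def test_rms_hand_example(self):
        assert rms_error(_ds([3.0, 4.0])) == pytest.approx(math.sqrt(12.5))
        assert rms_error(_ds([0.0] * 4)) == 0.0

    def test_rms_exceeds_population_sd_under_bias(self):
        d = np.random.default_rng(2).normal(2.0, 1.0, 200)
        assert rms_error(_ds(d)) > float(np.std(d))

    @given(
        arrays(
            float,
            st.integers(min_value=2, max_value=40),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_rms_identity_bias_squared_plus_population_variance(self, d):
        ds = _ds(d)
        rms2 = rms_error(ds) ** 2
        assert rms2 == pytest.approx(np.mean(d) ** 2 + np.var(d), rel=1e-9, abs=1e-9)

    def test_median_bias_bounded_under_single_outlier_while_mean_is_not(self):
        base = np.arange(1.0, 22.0)  # 21 points, median 11
        corrupted = base.copy()
        corrupted[-1] = 1e9
        assert abs(robust_bias(_ds(corrupted)) - robust_bias(_ds(base))) <= 1.0
        assert bland_altman_loa(_ds(corrupted))[0] > 1e6


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_correlation(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_example_matches_pearson_on_hand_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [10.0, 30.0, 30.0, 20.0]
        rank_x = [1.0, 2.5, 2.5, 4.0]
        rank_y = [1.0, 3.5, 3.5, 2.0]
        expected = np.corrcoef(rank_x, rank_y)[0, 1]
        assert spearman_correlation(x, y) == pytest.approx(expected)

    def test_zero_rank_variance_is_an_error(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRCV:
    def test_worked_example_with_biological_component(self):
        r = reference_change_value(10.0, 5.0, 1.96)
        assert r.cv_total == pytest.approx(math.sqrt(125.0))
        assert r.rcv_pct == pytest.approx(30.99, abs=0.01)

    def test_analytic_only(self):
        assert reference_change_value(10.0, 0.0, 1.96).rcv_pct == pytest.approx(
            math.sqrt(2) * 1.96 * 10.0
        )

    def test_zero_cvs_give_zero_rcv(self):
        assert reference_change_value(0.0, 0.0).rcv_pct == 0.0

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            reference_change_value(-1.0, 5.0)

    def test_rcv_dominates_each_component(self):
        r = reference_change_value(7.0, 3.0, 2.0)
        assert r.rcv_pct >= math.sqrt(2) * 2.0 * 7.0


def test_summarize_agreement_is_consistent_with_parts(small_table):
    s = summarize_agreement(small_table, "TRV", "CL1", "DL", scale="nominal", B=200, seed=4)
    ds = paired_differences(small_table, "TRV", "CL1", "DL")
    assert s.n == ds.n == 3
    assert s.bias == pytest.approx(robust_bias(ds, "nominal"))
    assert s.precision * SQRT2 == pytest.approx(s.precision_unscaled)
    assert s.relative_yield_pct == 100.0
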