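"""Separation, local Lyapunov exponents, summaries, trends, crossings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuttleflow import (
    DualTrace,
    EmptyInputError,
    InvalidInputError,
    InvalidParameterError,
    LyapunovSeries,
    LyapunovSummary,
    crossing_count,
    lambda_trend,
    local_log_slope,
    percentile_summary,
    separation,
)


def make_trace(s1, s2, dt=0.05):
    t = np.arange(len(s1)) * dt
    return DualTrace(times=t, s1=np.asarray(s1, float), s2=np.asarray(s2, float))


class TestDualTraceValidation:
    def test_rejects_short_and_nonuniform(self):
        with pytest.raises(InvalidInputError):
            make_trace(np.ones(5), np.ones(5))
        t = np.array([0.0, 1.0, 2.0, 3.1, 4.0, 5.0, 6.0, 7.0])
        with pytest.raises(InvalidInputError):
            DualTrace(times=t, s1=np.ones(8), s2=np.ones(8))

    def test_rejects_retreating_fronts(self):
        s = np.linspace(0, 1e-2, 20)
        bad = s.copy()
        bad[10] = bad[9] - 1e-3
        with pytest.raises(InvalidInputError):
            make_trace(s, bad)
        # but small decreases within the stated measurement tolerance pass
        t = np.arange(20) * 0.1
        DualTrace(times=t, s1=s, s2=bad, monotone_tol=2e-3)


class TestSeparation:
    def test_identical_channels_fully_masked(self):
        s = np.linspace(0, 1e-2, 50)
        series = separation(make_trace(s, s), floor=1e-6)
        assert np.all(series.separation == 0)
        assert not series.valid_mask.any()
        assert series.is_empty

    def test_swap_symmetry(self):
        s1 = np.linspace(0, 1e-2, 50)
        s2 = np.linspace(0, 0.8e-2, 50)
        a = separation(make_trace(s1, s2), floor=1e-6)
        b = separation(make_trace(s2, s1), floor=1e-6)
        assert np.array_equal(a.separation, b.separation)
        assert np.array_equal(a.valid_mask, b.valid_mask)

    def test_exponential_gives_linear_log(self, exponential_trace):
        lam0 = 0.3
        trace = exponential_trace(lam0)
        series = separation(trace, floor=1e-9)
        slopes = np.diff(series.log_separation) / np.diff(series.times)
        assert np.allclose(slopes, lam0, rtol=1e-9)

    def test_floor_must_be_positive(self, exponential_trace):
        with pytest.raises(InvalidParameterError):
            separation(exponential_trace(0.1), floor=0.0)


class TestLocalLogSlope:
    @pytest.mark.parametrize("window", [5, 7, 9, 11])
    @pytest.mark.parametrize("lam0", [0.01, 0.1, 1.0])
    def test_exact_recovery_for_exponential(self, exponential_trace, window, lam0):
        """Noiseless exponential separation: every local slope equals lambda0."""
        series = separation(exponential_trace(lam0), floor=1e-9)
        result = local_log_slope(series, window=window, degree=4)
        assert np.all(np.abs(result.lambda_local - lam0) <= 1e-9 * lam0)

    def test_quartic_log_separation_is_exact(self):
        """A degree-4 fit reproduces the analytic derivative of a quartic."""
        n, dt = 200, 0.1
        t = np.arange(n) * dt
        coeffs = [0.3, 0.02, -4e-4, 1e-5]  # log D = -8 + 0.3 t + ...
        log_d = -8 + sum(c * t ** (k + 1) for k, c in enumerate(coeffs))
        d = np.exp(log_d)
        trace = make_trace(np.ones(n) + d, np.ones(n), dt=dt)
        series = separation(trace, floor=1e-12)
        result = local_log_slope(series, window=7, degree=4)
        centers = t[3 : n - 3]
        exact = sum((k + 1) * c * centers**k for k, c in enumerate(coeffs))
        assert np.max(np.abs(result.lambda_local - exact) / np.abs(exact)) < 1e-6

    def test_window_count_law(self, exponential_trace):
        for n in (156, 200, 306):
            series = separation(exponential_trace(0.2, n=n), floor=1e-9)
            result = local_log_slope(series, window=7)
            assert result.lambda_local.size == n - 6

    def test_masked_windows_are_skipped(self):
        n = 60
        s2 = np.ones(n)
        d = np.full(n, 1e-3)
        d[25:30] = 1e-8  # dips below floor mid-run
        t = np.arange(n) * 0.05
        trace = DualTrace(times=t, s1=s2 + d, s2=s2, monotone_tol=1.0)
        series = separation(trace, floor=1e-6)
        result = local_log_slope(series, window=7)
        assert result.lambda_local.size == (25 - 6) + (n - 30 - 6)

    def test_parameter_validation(self, exponential_trace):
        series = separation(exponential_trace(0.1), floor=1e-9)
        with pytest.raises(InvalidParameterError):
            local_log_slope(series, window=6)
        with pytest.raises(InvalidParameterError):
            local_log_slope(series, window=3, degree=4)

    def test_all_masked_yields_empty_series(self):
        s = np.linspace(0, 1e-2, 50)
        series = separation(make_trace(s, s), floor=1e-6)
        result = local_log_slope(series)
        assert result.is_empty

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        shift=st.floats(-50.0, 50.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_time_shift_and_scale_equivariance(self, shift, scale):
        """Shifting time changes nothing; scaling both fronts changes nothing."""
        rng = np.random.default_rng(7)
        n, dt = 80, 0.05
        t = np.arange(n) * dt
        d = 1e-4 * np.exp(0.5 * t) * np.exp(0.05 * rng.standard_normal(n))
        s2 = np.linspace(0.0, 1e-2, n)
        s1 = s2 + d
        base = local_log_slope(separation(DualTrace(times=t, s1=s1, s2=s2), floor=1e-9))
        shifted = local_log_slope(
            separation(DualTrace(times=t + abs(shift), s1=s1, s2=s2), floor=1e-9)
        )
        scaled = local_log_slope(
            separation(DualTrace(times=t, s1=scale * s1, s2=scale * s2), floor=1e-9 * scale)
        )
        assert np.allclose(base.lambda_local, shifted.lambda_local, rtol=1e-6, atol=1e-9)
        assert np.allclose(base.lambda_local, scaled.lambda_local, rtol=1e-6, atol=1e-9)


class TestPercentileSummary:
    def test_constant_series(self):
        series = LyapunovSeries(times=np.arange(5.0), lambda_local=np.full(5, 2.5))
        assert percentile_summary(series, 0.75).lambda_q == 2.5
        assert percentile_summary(series, 0.1).lambda_q == 2.5

    def test_linear_interpolation_convention(self):
        series = LyapunovSeries(times=np.arange(4.0), lambda_local=np.array([1.0, 2.0, 3.0, 4.0]))
        assert percentile_summary(series, 0.75).lambda_q == pytest.approx(3.25)

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(0)
        series = LyapunovSeries(times=np.arange(100.0), lambda_local=rng.standard_normal(100))
        assert percentile_summary(series, 0.75).lambda_q >= percentile_summary(series, 0.5).lambda_q

    def test_positive_only_restriction(self):
        series = LyapunovSeries(
            times=np.arange(4.0), lambda_local=np.array([-1.0, 1.0, 2.0, 3.0])
        )
        full = percentile_summary(series, 0.5)
        pos = percentile_summary(series, 0.5, positive_only=True)
        assert pos.lambda_q == 2.0
        assert pos.n_exponents == 3
        assert full.lambda_q < pos.lambda_q

    def test_empty_series_raises(self):
        empty = LyapunovSeries(times=np.empty(0), lambda_local=np.empty(0))
        with pytest.raises(EmptyInputError):
            percentile_summary(empty)


class TestLambdaTrend:
    def test_exact_line(self):
        pairs = [
            (x, LyapunovSummary(lambda_q=2.0 * x + 1.0, n_exponents=10)) for x in (0.5, 1.0, 2.0)
        ]
        trend = lambda_trend(pairs)
        assert trend.slope == pytest.approx(2.0)
        assert trend.stderr == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        pairs = [
            (x, LyapunovSummary(lambda_q=float(rng.uniform(0, 2)), n_exponents=5))
            for x in (1.0, 2.0, 3.0, 4.0)
        ]
        a = lambda_trend(pairs)
        b = lambda_trend(pairs[::-1])
        assert a.slope == pytest.approx(b.slope)
        assert a.stderr == pytest.approx(b.stderr)

    def test_needs_two_distinct_conditions(self):
        pairs = [(1.0, LyapunovSummary(lambda_q=0.5, n_exponents=5))] * 3
        with pytest.raises(InvalidInputError):
            lambda_trend(pairs)


class TestCrossingCount:
    def test_constant_offset_never_crosses(self):
        s2 = np.linspace(0, 1e-2, 40)
        assert crossing_count(make_trace(s2 + 1e-3, s2)) == 0

    def test_constructed_k_crossings(self):
        n, dt = 120, 0.05
        t = np.arange(n) * dt
        base = np.linspace(0, 2e-2, n)
        wobble = 1e-4 * np.sin(2 * np.pi * t / (t[-1] / 3.5))  # 7 zero crossings
        k = np.count_nonzero(np.diff(np.sign(wobble)[np.sign(wobble) != 0]))
        trace = DualTrace(times=t, s1=base + np.abs(wobble) * 0 + wobble + 2e-4 * 0, s2=base,
                          monotone_tol=1e-4)
        assert crossing_count(trace) == k

    def test_floor_suppresses_subresolution_crossings(self):
        s2 = np.linspace(0, 1e-2, 40)
        jitter = 1e-8 * (-1.0) ** np.arange(40)
        trace = DualTrace(times=np.arange(40) * 0.1, s1=s2 + jitter, s2=s2, monotone_tol=1e-7)
        assert crossing_count(trace, floor=1e-6) == 0
        assert crossing_count(trace) > 0
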