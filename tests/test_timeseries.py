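"""Smoothing, season detection and iEVI integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evisoscape.synthetic import DoubleLogisticParams, double_logistic
from evisoscape.timeseries import (
    EviSeries,
    GapTooLongError,
    GrowingSeason,
    SeasonNotFoundError,
    SeriesTooShortError,
    SmoothingConfig,
    aggregate_to_intervals,
    compute_ievi,
    detect_growing_season,
    ievi_covariates,
    smooth_upper_envelope_sg,
    split_seasons,
)


def series_16day(values, start="2007-01-09", site="t"):
    n = len(values)
    times = pd.Timestamp(start) + pd.to_timedelta(16 * np.arange(n), unit="D")
    return EviSeries(site, times, np.asarray(values, dtype=float))


def triangle(n=23, peak=1.0, offset=0.0):
    """Symmetric triangular pulse over n composites, peak mid-series."""
    half = (n - 1) / 2
    v = peak * (1 - np.abs(np.arange(n) - half) / half) + offset
    s = series_16day(v)
    return EviSeries(s.site_id, s.times, s.values, smoothed=s.values)


class TestSmoothing:
    def test_constant_series_reproduced(self):
        s = series_16day(np.full(23, 0.5))
        out = smooth_upper_envelope_sg(s, SmoothingConfig())
        assert np.allclose(out.smoothed, 0.5, atol=1e-12)

    def test_quadratic_reproduced(self):
        t = 16.0 * np.arange(30)
        v = 0.3 + 1e-3 * t - 2e-6 * t**2
        s = series_16day(v)
        out = smooth_upper_envelope_sg(
            s, SmoothingConfig(envelope_iterations=0))
        assert np.max(np.abs(out.smoothed - v)) < 1e-9

    def test_matches_per_window_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        v = np.sin(np.linspace(0, 3, 40)) + 0.05 * rng.normal(size=40)
        s = series_16day(v)
        cfg = SmoothingConfig(envelope_iterations=0)
        out = smooth_upper_envelope_sg(s, cfg)
        t = s.t_days
        for i in range(len(v)):  # oracle: explicit polyfit per window
            lo, hi = max(0, i - cfg.window), min(len(v), i + cfg.window + 1)
            coef = np.polyfit(t[lo:hi] - t[i], v[lo:hi], cfg.poly_degree)
            assert out.smoothed[i] == pytest.approx(coef[-1], abs=1e-9)

    def test_envelope_recovers_cloud_spikes(self):
        dl = DoubleLogisticParams()
        t = 8.0 + 16.0 * np.arange(23)
        truth = double_logistic(t, dl)
        spiked = truth.copy()
        idx = [5, 8, 11, 14, 17]
        spiked[idx] -= 0.3
        s = series_16day(spiked)
        mae = {}
        for iters in (0, 3):
            out = smooth_upper_envelope_sg(
                s, SmoothingConfig(envelope_iterations=iters))
            mae[iters] = np.mean(np.abs(out.smoothed[idx] - truth[idx]))
        assert mae[3] < mae[0]

    def test_weight_mass_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        v = 0.5 + 0.3 * np.sin(np.linspace(0, 6, 46)) \
            - (rng.random(46) < 0.2) * 0.3
        s = series_16day(v)
        masses = []
        for iters in range(5):
            out = smooth_upper_envelope_sg(
                s, SmoothingConfig(envelope_iterations=iters))
            w = out.weights
            assert np.all(w > 0) and np.all(w <= 1)
            masses.append(w.sum())
        assert np.all(np.diff(masses) <= 1e-12)

    def test_too_short_series_raises(self):
        with pytest.raises(SeriesTooShortError, match="need >= 11"):
            smooth_upper_envelope_sg(series_16day(np.full(8, 0.4)))

    def test_gap_fill_and_long_gap_error(self):
        v = np.full(23, 0.5)
        v[10:12] = np.nan
        out = smooth_upper_envelope_sg(series_16day(v))
        assert np.allclose(out.smoothed, 0.5, atol=1e-12)
        assert out.filled is not None and out.filled.sum() == 2
        v[10:14] = np.nan
        with pytest.raises(GapTooLongError, match="4 consecutive"):
            smooth_upper_envelope_sg(series_16day(v))


class TestSeasonDetection:
    def test_triangular_pulse_analytic_crossings(self):
        s = triangle()
        season = detect_growing_season(s, season_threshold=0.167)
        # linear rise from 0 at t[0] to 1 at the peak: level 0.167 is
        # crossed at exactly 0.167 of the half-span on each limb
        t = s.t_days
        half_span = t[11] - t[0]
        start_expect = t[0] + 0.167 * half_span
        end_expect = t[22] - 0.167 * half_span
        origin = s.times[0]
        got_start = (season.start_time - origin).value / 86_400e9
        got_end = (season.end_time - origin).value / 86_400e9
        assert got_start == pytest.approx(start_expect, abs=1e-9)
        assert got_end == pytest.approx(end_expect, abs=1e-9)
        assert season.base_level == pytest.approx(0.0)
        assert season.amplitude == pytest.approx(1.0)

    def test_flat_series_no_season(self):
        s = series_16day(np.full(23, 0.4))
        s = EviSeries(s.site_id, s.times, s.values, smoothed=s.values)
        with pytest.raises(SeasonNotFoundError):
            detect_growing_season(s)

    @given(offset=st.floats(-5, 5))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_additive_offset_invariance(self, offset):
        base = detect_growing_season(triangle())
        shifted = detect_growing_season(triangle(offset=offset))
        assert shifted.length_days == pytest.approx(base.length_days,
                                                    abs=1e-6)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-9)


class TestIevi:
    def test_rectangle_area(self):
        s = series_16day(np.full(30, 0.4))
        s = EviSeries(s.site_id, s.times, s.values, smoothed=s.values)
        start = s.times[2]
        end = s.times[20]
        season = GrowingSeason(start, end, 0.0, 0.4)
        L = (end - start).value / 86_400e9
        got = compute_ievi(s, season, start_fraction=1 / 6)
        assert got == pytest.approx(0.4 * (1 - 1 / 6) * L, rel=1e-12)

    def test_all_zero_curve(self):
        s = series_16day(np.zeros(30))
        s = EviSeries(s.site_id, s.times, s.values, smoothed=s.values)
        season = GrowingSeason(s.times[2], s.times[20], 0.0, 1.0)
        assert compute_ievi(s, season) == 0.0

    def test_double_logistic_matches_dense_quadrature(self):
        dl = DoubleLogisticParams(base=0.1, amplitude=0.5, start_day=70,
                                  end_day=300)
        t = 8.0 + 16.0 * np.arange(23)
        v = double_logistic(t, dl)
        s = series_16day(v)
        s = EviSeries(s.site_id, s.times, s.values, smoothed=v)
        season = detect_growing_season(s)
        got = compute_ievi(s, season)
        # oracle: 0.1-day trapezoid on the analytic curve
        origin = s.times[0]
        sd = (season.start_time - origin).value / 86_400e9 + t[0]
        ed = (season.end_time - origin).value / 86_400e9 + t[0]
        lo = sd + (ed - sd) / 6
        grid = np.arange(lo, ed, 0.1)
        oracle = np.trapezoid(double_logistic(grid, dl), grid)
        assert got == pytest.approx(oracle, rel=5e-3)

    def test_season_outside_span_errors(self):
        s = series_16day(np.full(23, 0.4))
        s = EviSeries(s.site_id, s.times, s.values, smoothed=s.values)
        season = GrowingSeason(s.times[0] - pd.Timedelta(days=30),
                               s.times[5], 0.0, 1.0)
        with pytest.raises(ValueError, match="outside the series span"):
            compute_ievi(s, season)

    @given(scale=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_linear_scaling(self, scale):
        v = double_logistic(8.0 + 16.0 * np.arange(23),
                            DoubleLogisticParams())
        season = None
        vals = []
        for k in (1.0, scale):
            s = series_16day(k * v)
            s = EviSeries(s.site_id, s.times, s.values, smoothed=k * v)
            season = season or detect_growing_season(s)
            vals.append(compute_ievi(s, season))
        assert vals[1] == pytest.approx(scale * vals[0], rel=1e-9)


class TestAggregation:
    def _curve(self):
        v = double_logistic(8.0 + 16.0 * np.arange(23),
                            DoubleLogisticParams())
        s = series_16day(v)
        return EviSeries(s.site_id, s.times, s.values, smoothed=v)

    def test_partition_sums_to_whole(self):
        s = self._curve()
        a, m, b = s.times[2], s.times[11], s.times[20]
        whole = aggregate_to_intervals(s, [(a, b)])[0]
        parts = aggregate_to_intervals(s, [(a, m), (m, b)])
        assert parts.sum() == pytest.approx(whole, rel=1e-12)

    def test_matches_compute_ievi_on_season_tail(self):
        s = self._curve()
        season = detect_growing_season(s)
        lo = season.start_time + (season.end_time - season.start_time) / 6
        got = aggregate_to_intervals(s, [(lo, season.end_time)])[0]
        assert got == pytest.approx(compute_ievi(s, season), rel=1e-12)

    def test_monthly_partition_matches_dense_oracle(self):
        dl = DoubleLogisticParams()
        s = self._curve()
        months = [(pd.Timestamp(f"2007-{m:02d}-01"),
                   pd.Timestamp(f"2007-{m + 1:02d}-01")) for m in range(2, 12)]
        got = aggregate_to_intervals(s, months)
        t = s.t_days
        origin = s.times[0]
        for (a, b), g in zip(months, got):
            ad = (a - origin).value / 86_400e9
            bd = (b - origin).value / 86_400e9
            grid = np.linspace(ad, bd, 2000)
            oracle = np.trapezoid(np.interp(grid, t, s.smoothed), grid)
            assert g == pytest.approx(oracle, rel=1e-6)

    def test_interval_outside_span_names_interval(self):
        s = self._curve()
        bad = (s.times[20], s.times[-1] + pd.Timedelta(days=40))
        with pytest.raises(ValueError, match="interval 1"):
            aggregate_to_intervals(s, [(s.times[0], s.times[3]), bad])

    def test_covariates_clip_to_season(self):
        s = self._curve()
        season = detect_growing_season(s)
        before = season.start_time - pd.Timedelta(days=5)
        after = season.end_time  # saturates at the complete-season value
        x = ievi_covariates(s, season, [before, after])
        assert x[0] == 0.0
        assert x[1] == pytest.approx(compute_ievi(s, season), rel=1e-12)


def test_split_seasons_blocks_and_padding():
    v = np.tile(np.arange(23, dtype=float), 3)
    s = series_16day(v, start="2007-01-09")
    blocks = split_seasons(s, pad_seasons=1)
    assert len(blocks) == 1
    label, sub = blocks[0]
    assert len(sub) == 23
    assert np.array_equal(sub.values, np.arange(23.0))
    with pytest.raises(ValueError, match="multiple"):
        split_seasons(series_16day(np.zeros(25)))
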