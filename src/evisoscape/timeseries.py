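"""Smoothing and integration of 16-day EVI composite time series.

MODIS vegetation-index composites are negatively biased by residual cloud
and aerosol contamination, so the seasonal signal is recovered with an
iterative *upper-envelope* Savitzky–Golay filter: a weighted local
polynomial fit in which points falling below the current fit are
progressively down-weighted.  From the smoothed curve the growing season is
delimited at a fixed fraction of the seasonal amplitude, and the
growing-season integrated EVI (iEVI, EVI·days) is the area under the curve
from one sixth of the season through its end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EviSeries",
    "SmoothingConfig",
    "GrowingSeason",
    "SeriesTooShortError",
    "SeasonNotFoundError",
    "GapTooLongError",
    "smooth_upper_envelope_sg",
    "detect_growing_season",
    "compute_ievi",
    "aggregate_to_intervals",
    "ievi_covariates",
    "split_seasons",
]

NS_PER_DAY = 86_400e9


class SeriesTooShortError(ValueError):
    """Series has fewer points than the smoothing window requires."""


class SeasonNotFoundError(ValueError):
    """Seasonal amplitude below the detection minimum."""


class GapTooLongError(ValueError):
    """More consecutive missing composites than can be gap-filled."""


def _as_datetimes(times) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(list(times)))
    if len(idx) >= 2 and not idx.is_monotonic_increasing:
        raise ValueError("times must be strictly increasing")
    if len(idx) >= 2 and (np.diff(idx.asi8) <= 0).any():
        raise ValueError("times must be strictly increasing")
    return idx


def _days(times: pd.DatetimeIndex, origin=None) -> np.ndarray:
    """Times as float days since ``origin`` (default: first sample)."""
    if origin is None:
        origin = times[0]
    return (times.asi8 - pd.Timestamp(origin).value) / NS_PER_DAY


@dataclass
class EviSeries:
    """One site's (or pixel's) dated EVI composite series.

    ``values`` may contain NaN for missing composites; they are linearly
    gap-filled before smoothing (at most 3 consecutive gaps).
    """

    site_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    smoothed: np.ndarray | None = None
    weights: np.ndarray | None = None
    filled: np.ndarray | None = None  # True where a value was gap-filled

    def __post_init__(self):
        self.times = _as_datetimes(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times),):
            raise ValueError("values and times must have equal length")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError("values must be finite or NaN (missing)")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.values.shape:
                raise ValueError("smoothed must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t_days(self) -> np.ndarray:
        return _days(self.times)

    def year_slice(self, year: int) -> "EviSeries":
        m = self.times.year == year
        return EviSeries(
            self.site_id,
            self.times[m],
            self.values[m],
            None if self.smoothed is None else self.smoothed[m],
        )


@dataclass(frozen=True)
class SmoothingConfig:
    """Upper-envelope Savitzky–Golay settings (TIMESAT conventions).

    ``window`` is the half-window: number of points on each side of the
    fitted point, so the full window holds ``2*window + 1`` samples.
    """

    window: int = 5
    poly_degree: int = 2
    envelope_iterations: int = 3
    adaptation_strength: float = 3.0
    max_gap: int = 3

    def __post_init__(self):
        if self.window < self.poly_degree:
            raise ValueError("window must be >= poly_degree")
        if self.envelope_iterations < 0:
            raise ValueError("envelope_iterations must be >= 0")
        if self.adaptation_strength <= 0:
            raise ValueError("adaptation_strength must be > 0")


@dataclass(frozen=True)
class GrowingSeason:
    """Growing-season bounds from amplitude-threshold crossings."""

    start_time: pd.Timestamp
    end_time: pd.Timestamp
    base_level: float
    amplitude: float
    season_threshold: float = 0.167

    def __post_init__(self):
        if not self.start_time < self.end_time:
            raise ValueError("start_time must precede end_time")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not 0 < self.season_threshold < 1:
            raise ValueError("season_threshold must be in (0,1)")

    @property
    def length_days(self) -> float:
        return (self.end_time - self.start_time).value / NS_PER_DAY


def fill_gaps(series: EviSeries, max_gap: int = 3) -> EviSeries:
    """Linearly interpolate NaN values; error on runs longer than max_gap."""
    v = series.values
    missing = np.isnan(v)
    if not missing.any():
        return replace(series, filled=np.zeros(len(v), bool))
    # longest run of consecutive NaN
    run, longest = 0, 0
    for m in missing:
        run = run + 1 if m else 0
        longest = max(longest, run)
    if longest > max_gap:
        raise GapTooLongError(
            f"{longest} consecutive missing composites (max {max_gap})"
        )
    if missing[0] or missing[-1]:
        raise GapTooLongError("missing composites at series boundary")
    t = series.t_days
    v = v.copy()
    v[missing] = np.interp(t[missing], t[~missing], v[~missing])
    return replace(series, values=v, filled=missing)


def _local_poly_fit(t: np.ndarray, v: np.ndarray, w: np.ndarray,
                    window: int, degree: int) -> np.ndarray:
    """Weighted local polynomial fit evaluated at every sample point.

    Boundary points use truncated asymmetric windows.  Handles uneven time
    spacing (the actual day axis, not sample index, is the regressor).
    """
    n = len(v)
    fit = np.empty(n)
    sw = np.sqrt(w)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        tt = t[lo:hi] - t[i]
        deg = min(degree, hi - lo - 1)
        A = np.vander(tt, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(A * sw[lo:hi, None], v[lo:hi] * sw[lo:hi],
                                   rcond=None)
        fit[i] = coef[0]  # polynomial evaluated at tt = 0
    return fit


def smooth_upper_envelope_sg(series: EviSeries,
                             cfg: SmoothingConfig = SmoothingConfig()
                             ) -> EviSeries:
    """Upper-envelope Savitzky–Golay smoothing of an EVI series.

    After each envelope iteration, points lying below the current fit are
    down-weighted with

        w_new = min(w_old, 1 / (1 + (gap / (s * sigma))^2))

    where ``gap`` is the distance below the fit, ``s`` the adaptation
    strength and ``sigma`` the residual standard deviation, so the curve
    adapts toward the upper envelope of the data.  Weights of points at or
    above the fit are unchanged; total weight mass never increases.
    """
    series = fill_gaps(series, cfg.max_gap)
    n = len(series)
    if n < 2 * cfg.window + 1:
        raise SeriesTooShortError(
            f"need >= {2 * cfg.window + 1} points for window={cfg.window}, "
            f"got {n}"
        )
    t, v = series.t_days, series.values
    w = np.ones(n)
    fit = _local_poly_fit(t, v, w, cfg.window, cfg.poly_degree)
    for _ in range(cfg.envelope_iterations):
        resid = v - fit
        sigma = float(np.std(resid))
        if sigma == 0.0:
            break
        gap = np.where(resid < 0, -resid, 0.0)
        kernel = 1.0 / (1.0 + (gap / (cfg.adaptation_strength * sigma)) ** 2)
        w = np.minimum(w, kernel)
        fit = _local_poly_fit(t, v, w, cfg.window, cfg.poly_degree)
    return replace(series, smoothed=fit, weights=w)


def _require_smoothed(series: EviSeries) -> np.ndarray:
    if series.smoothed is None:
        raise ValueError("series has no smoothed curve; smooth it first")
    return series.smoothed


def detect_growing_season(series: EviSeries,
                          season_threshold: float = 0.167,
                          min_amplitude: float = 0.01) -> GrowingSeason:
    """Delimit the growing season on the smoothed curve.

    The base level is the mean of the pre-season and post-season minima of
    the smoothed curve; start/end are the times where the curve crosses
    ``base + season_threshold * amplitude`` on the rising and falling limbs
    (linearly interpolated between composites).  Threshold crossings are
    amplitude-relative, so detection is invariant to additive offsets.
    """
    s = _require_smoothed(series)
    t = series.t_days
    i_max = int(np.argmax(s))
    left_min = float(np.min(s[: i_max + 1]))
    right_min = float(np.min(s[i_max:]))
    base = 0.5 * (left_min + right_min)
    amplitude = float(s[i_max]) - base
    if amplitude <= min_amplitude:
        raise SeasonNotFoundError(
            f"seasonal amplitude {amplitude:.4f} <= minimum {min_amplitude}"
        )
    level = base + season_threshold * amplitude

    def cross(i0: int, i1: int) -> float:
        """Linear interpolation of the level crossing in segment [i0, i1]."""
        f = (level - s[i0]) / (s[i1] - s[i0])
        return t[i0] + f * (t[i1] - t[i0])

    # rising limb: walk left from the peak to the last point below the level
    start_d = t[0]
    for j in range(i_max - 1, -1, -1):
        if s[j] < level <= s[j + 1] or (s[j] < level and s[j + 1] >= level):
            start_d = cross(j, j + 1)
            break
    # falling limb: walk right from the peak
    end_d = t[-1]
    for j in range(i_max, len(s) - 1):
        if s[j] >= level > s[j + 1]:
            end_d = cross(j, j + 1)
            break
    origin = series.times[0]
    start = origin + pd.to_timedelta(start_d, unit="D")
    end = origin + pd.to_timedelta(end_d, unit="D")
    return GrowingSeason(start, end, base, amplitude, season_threshold)


def _integrate_segment(series: EviSeries, t_lo: float, t_hi: float) -> float:
    """Trapezoidal integral of the smoothed piecewise-linear curve (days)."""
    s = _require_smoothed(series)
    t = series.t_days
    eps = 1e-9
    if t_lo < t[0] - eps or t_hi > t[-1] + eps:
        raise ValueError(
            f"integration bounds [{t_lo:.2f}, {t_hi:.2f}] days outside the "
            f"series span [{t[0]:.2f}, {t[-1]:.2f}]"
        )
    if t_hi <= t_lo:
        return 0.0
    inner = t[(t > t_lo) & (t < t_hi)]
    grid = np.concatenate(([t_lo], inner, [t_hi]))
    y = np.interp(grid, t, s)
    return float(np.trapezoid(y, grid))


def compute_ievi(series: EviSeries, season: GrowingSeason,
                 start_fraction: float = 1.0 / 6.0) -> float:
    """Growing-season integrated EVI (EVI·days).

    Area under the smoothed curve from ``start + start_fraction * length``
    through the season end, with partial-interval handling at both ends.
    """
    origin = series.times[0]
    s_d = (season.start_time - origin).value / NS_PER_DAY
    e_d = (season.end_time - origin).value / NS_PER_DAY
    t_lo = s_d + start_fraction * (e_d - s_d)
    return _integrate_segment(series, t_lo, e_d)


def aggregate_to_intervals(series: EviSeries, intervals) -> np.ndarray:
    """Integrated EVI over each (start, end) date interval.

    Intervals must be non-overlapping and within the series span; the sum
    over a partition of a span equals the integral over the span.
    """
    origin = series.times[0]
    spans = []
    for k, (a, b) in enumerate(intervals):
        a, b = pd.Timestamp(a), pd.Timestamp(b)
        if not a < b:
            raise ValueError(f"interval {k} ({a.date()}..{b.date()}) ill-ordered")
        spans.append(((a - origin).value / NS_PER_DAY,
                      (b - origin).value / NS_PER_DAY))
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        if a1 < b0 - 1e-9:
            raise ValueError("intervals overlap")
    out = np.empty(len(spans))
    for k, (a, b) in enumerate(spans):
        try:
            out[k] = _integrate_segment(series, a, b)
        except ValueError as exc:
            raise ValueError(f"interval {k}: {exc}") from None
    return out


def split_seasons(series: EviSeries, composites_per_season: int = 23,
                  pad_seasons: int = 0):
    """Split a composite series into consecutive season blocks.

    A block holds ``composites_per_season`` composites (23 for a 16-day
    product, one seasonal cycle).  ``pad_seasons`` blocks at each end are
    dropped (they exist only so interior blocks are smoothed with full
    windows).  Returns ``[(label, sub_series), ...]`` where the label is
    the calendar year in which the block starts.  Smoothed values and
    weights, when present, are carried into the sub-series.
    """
    n = len(series)
    m = composites_per_season
    if n % m != 0:
        raise ValueError(
            f"series length {n} is not a multiple of {m} composites/season"
        )
    blocks = []
    n_blocks = n // m
    for b in range(pad_seasons, n_blocks - pad_seasons):
        sl = slice(b * m, (b + 1) * m)
        sub = EviSeries(
            series.site_id,
            series.times[sl],
            series.values[sl],
            None if series.smoothed is None else series.smoothed[sl],
            None if series.weights is None else series.weights[sl],
        )
        blocks.append((int(series.times[sl.start].year), sub))
    return blocks


def ievi_covariates(series: EviSeries, season: GrowingSeason, when,
                    start_fraction: float = 1.0 / 6.0) -> np.ndarray:
    """Cumulative in-season iEVI at given dates — the model covariate x.

    For each date, the integral of the smoothed curve from the season
    integration start (``start + start_fraction * length``) up to that date,
    clipped to the season: dates before the integration start give 0, dates
    after the season end give the complete-season value.
    """
    origin = series.times[0]
    s_d = (season.start_time - origin).value / NS_PER_DAY
    e_d = (season.end_time - origin).value / NS_PER_DAY
    t_lo = s_d + start_fraction * (e_d - s_d)
    out = []
    for d in np.atleast_1d(np.asarray(pd.to_datetime(when))):
        td = (pd.Timestamp(d) - origin).value / NS_PER_DAY
        td = min(max(td, t_lo), e_d)
        out.append(_integrate_segment(series, t_lo, td))
    return np.asarray(out)
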