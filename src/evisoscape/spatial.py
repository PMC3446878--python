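"""Elevation-gradient interpolation and 250 m isoscape rasterisation.

Site-level iEVI–δ¹⁸O functions are extended off-site with two ingredients:
the nearest (in elevation) anchor site's function, with its kink location b
rescaled to the target pixel's growing-season iEVI, and a linear
δ¹⁸O–elevation relation (the altitude effect, ‰ per m) fitted on the anchor
predictions, whose residual between pixel and anchor elevation adjusts the
prediction.  Rasters are xarray DataArrays carrying an affine transform and
a CRS label; per-pixel values are produced by exactly the same scalar
pipeline used at the site level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .model import IsoModelParams, predict_d18o, rescale_b
from .timeseries import (
    EviSeries,
    SmoothingConfig,
    SeasonNotFoundError,
    GapTooLongError,
    compute_ievi,
    detect_growing_season,
    ievi_covariates,
    smooth_upper_envelope_sg,
)

__all__ = [
    "Station",
    "AnchorFunction",
    "ElevationRelation",
    "IsoscapeGrid",
    "GridMismatchError",
    "fit_elevation_relation",
    "predict_at_elevation",
    "predict_pixel",
    "build_isoscape_raster",
    "neighborhood_sensitivity",
]

NODATA = -9999.0


class GridMismatchError(ValueError):
    """Input rasters are not co-registered."""


@dataclass(frozen=True)
class Station:
    """A precipitation-collection site."""

    site_id: str
    lon: float
    lat: float
    elevation: float  # m a.s.l.
    land_cover: str | None = None

    def __post_init__(self):
        if not -430.0 <= self.elevation <= 9000.0:
            raise ValueError(f"implausible elevation {self.elevation} m")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError("invalid coordinates")


@dataclass(frozen=True)
class AnchorFunction:
    """A fitted site function usable as a spatial anchor."""

    station: Station
    params: IsoModelParams
    model_season_ievi: float  # complete-growing-season iEVI of the model season

    def __post_init__(self):
        if not self.model_season_ievi > 0:
            raise ValueError("model-season iEVI must be positive")


@dataclass(frozen=True)
class ElevationRelation:
    """Linear δ¹⁸O–elevation relation for one time step."""

    time_step: tuple
    intercept: float  # permil
    lapse: float  # permil per m
    r_squared: float
    elev_range: tuple = (-np.inf, np.inf)

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.lapse)):
            raise ValueError("non-finite relation coefficients")


@dataclass
class IsoscapeGrid:
    """Georeferenced raster of predicted δ¹⁸O for one time step.

    ``data`` is a (y, x) DataArray in ‰, NaN where masked; ``transform``
    uses rasterio ordering (xres, 0, x_origin, 0, -yres, y_origin).
    """

    data: xr.DataArray
    crs: str
    transform: tuple
    time_step: tuple
    nodata: float = NODATA

    def __post_init__(self):
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0 or abs(abs(a) - abs(e)) > 1e-6:
            raise ValueError("transform must be north-up with square cells")

    @property
    def cell_size(self) -> float:
        return abs(self.transform[0])


def fit_elevation_relation(anchor_predictions, time_step=None
                           ) -> ElevationRelation:
    """OLS of δ¹⁸O on elevation for one time step.

    ``anchor_predictions`` is a sequence of (elevation_m, d18o_permil).
    """
    pts = [(float(z), float(v)) for z, v in anchor_predictions]
    if len(pts) < 2:
        raise ValueError("need >= 2 anchors")
    z = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.ptp(z) == 0:
        raise ValueError("degenerate: identical anchor elevations")
    if len(pts) == 2:
        lapse = (v[1] - v[0]) / (z[1] - z[0])
        intercept = v[0] - lapse * z[0]
        r2 = 1.0
    else:
        res = stats.linregress(z, v)
        lapse, intercept = res.slope, res.intercept
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return ElevationRelation(time_step, float(intercept), float(lapse), r2,
                             (float(z.min()), float(z.max())))


def predict_at_elevation(relation: ElevationRelation, elevation: float,
                         warn_extrapolation: bool = False) -> float:
    """δ¹⁸O (‰) at an elevation from the fitted lapse relation."""
    lo, hi = relation.elev_range
    if warn_extrapolation and not lo <= elevation <= hi:
        warnings.warn(
            f"elevation {elevation} m outside anchor range [{lo}, {hi}] m",
            stacklevel=2,
        )
    return relation.intercept + relation.lapse * elevation


def _nearest_anchor(anchors, elevation: float) -> AnchorFunction:
    return min(anchors, key=lambda a: (abs(a.station.elevation - elevation),
                                       a.station.site_id))


def predict_pixel(series: EviSeries, elevation: float, anchors,
                  relation: ElevationRelation, time_step,
                  smoothing: SmoothingConfig = SmoothingConfig(),
                  season_threshold: float = 0.167,
                  start_fraction: float = 1.0 / 6.0) -> float:
    """Scalar prediction pipeline for one pixel (or site) and time step.

    Smooth the EVI series, delimit its growing season, take the nearest
    anchor (in elevation), rescale that anchor's b to the pixel's
    complete-season iEVI, evaluate the function at the pixel's cumulative
    iEVI for the time step's midpoint, and add the lapse-relation residual
    between pixel and anchor elevation.  Returns NaN when no season is
    detectable or the series is invalid.
    """
    try:
        sm = smooth_upper_envelope_sg(series, smoothing)
        season = detect_growing_season(sm, season_threshold)
        full_ievi = compute_ievi(sm, season, start_fraction=0.0)
    except (SeasonNotFoundError, GapTooLongError, ValueError):
        return float("nan")
    anchor = _nearest_anchor(anchors, elevation)
    b_new = rescale_b(anchor.params.b, anchor.model_season_ievi, full_ievi)
    params = _dc_replace(anchor.params, b=b_new)
    t0, t1 = pd.Timestamp(time_step[0]), pd.Timestamp(time_step[1])
    mid = t0 + (t1 - t0) / 2
    x = float(ievi_covariates(sm, season, [mid], start_fraction)[0])
    y = predict_d18o(params, x)
    y += (predict_at_elevation(relation, elevation)
          - predict_at_elevation(relation, anchor.station.elevation))
    return float(y)


def _check_registration(stack: xr.DataArray, dem: xr.DataArray):
    ts, td = stack.attrs.get("transform"), dem.attrs.get("transform")
    if stack.shape[-2:] != dem.shape:
        raise GridMismatchError(
            f"shape mismatch: EVI stack {stack.shape[-2:]} vs DEM {dem.shape}"
        )
    if ts is not None and td is not None and not np.allclose(ts, td):
        raise GridMismatchError(
            f"transform mismatch: EVI stack {tuple(ts)} vs DEM {tuple(td)}"
        )


def build_isoscape_raster(evi_stack: xr.DataArray, dem: xr.DataArray,
                          anchors, relation: ElevationRelation, time_step,
                          smoothing: SmoothingConfig = SmoothingConfig(),
                          season_threshold: float = 0.167,
                          start_fraction: float = 1.0 / 6.0) -> IsoscapeGrid:
    """Rasterise predicted δ¹⁸O over a co-registered EVI stack and DEM.

    ``evi_stack`` is a (time, y, x) DataArray whose ``time`` coordinate
    holds composite dates; ``dem`` a (y, x) DataArray of elevations.  Every
    pixel runs the scalar pipeline of :func:`predict_pixel`; pixels whose
    series are invalid or have no detectable season are masked (NaN).
    """
    _check_registration(evi_stack, dem)
    times = pd.DatetimeIndex(pd.to_datetime(evi_stack["time"].values))
    ny, nx = dem.shape
    out = np.full((ny, nx), np.nan)
    dem_v = np.asarray(dem.values, dtype=float)
    vals = np.asarray(evi_stack.values, dtype=float)
    for i in range(ny):
        for j in range(nx):
            series = EviSeries(f"px_{i}_{j}", times, vals[:, i, j])
            out[i, j] = predict_pixel(
                series, dem_v[i, j], anchors, relation, time_step,
                smoothing, season_threshold, start_fraction,
            )
    da = xr.DataArray(out, dims=("y", "x"),
                      coords={"y": dem.coords.get("y", np.arange(ny)),
                              "x": dem.coords.get("x", np.arange(nx))},
                      attrs={"units": "permil", "nodata": NODATA})
    transform = tuple(dem.attrs.get("transform",
                                    (250.0, 0.0, 0.0, 0.0, -250.0, 0.0)))
    crs = dem.attrs.get("crs", "unknown")
    return IsoscapeGrid(da, crs, transform, tuple(pd.Timestamp(t)
                                                  for t in time_step))


def _ring_offsets(dist: int):
    offs = []
    for di in range(-dist, dist + 1):
        for dj in range(-dist, dist + 1):
            if max(abs(di), abs(dj)) == dist:
                offs.append((di, dj))
    return offs


def neighborhood_sensitivity(evi_stack: xr.DataArray, dem: xr.DataArray,
                             site_pixels: dict, obs_by_site: dict,
                             predictability_fn, ring_cells: int = 1):
    """Focal- vs ring-pixel predictability difference Δr.

    For each site pixel, rerun the site's fit/predict cycle
    (``predictability_fn(series, obs) -> r``) using the EVI series of each
    pixel in the Chebyshev ring at ``ring_cells`` (1 ring cell = 250 m: 8
    pixels; 2 = 500 m: 16 pixels) and pool Δr = r(ring) − r(focal) across
    sites.  Returns a dict with the pooled mean, standard error, paired
    two-sided t-test p-value, the per-pixel Δr values and the number of
    ring pixels skipped for falling outside the raster.
    """
    _check_registration(evi_stack, dem)
    times = pd.DatetimeIndex(pd.to_datetime(evi_stack["time"].values))
    vals = np.asarray(evi_stack.values, dtype=float)
    ny, nx = dem.shape
    deltas, skipped = [], 0
    for site_id, (i, j) in site_pixels.items():
        obs = obs_by_site[site_id]
        focal = EviSeries(site_id, times, vals[:, i, j])
        r_focal = predictability_fn(focal, obs)
        for di, dj in _ring_offsets(ring_cells):
            ii, jj = i + di, j + dj
            if not (0 <= ii < ny and 0 <= jj < nx):
                skipped += 1
                continue
            ring = EviSeries(f"{site_id}_ring", times, vals[:, ii, jj])
            r_ring = predictability_fn(ring, obs)
            deltas.append(r_ring - r_focal)
    if skipped:
        warnings.warn(f"{skipped} ring pixels outside raster, skipped",
                      stacklevel=2)
    deltas = np.asarray(deltas, dtype=float)
    if len(deltas) == 0:
        raise ValueError("no ring pixels inside the raster")
    mean = float(np.mean(deltas))
    se = float(np.std(deltas, ddof=1) / np.sqrt(len(deltas))) \
        if len(deltas) > 1 else 0.0
    if len(deltas) > 1 and np.std(deltas) > 0:
        p = float(stats.ttest_1samp(deltas, 0.0).pvalue)
    else:
        p = 1.0
    return {
        "mean_delta_r": mean,
        "se": se,
        "p_value": p,
        "deltas": deltas,
        "n_ring_pixels": int(len(deltas)),
        "n_skipped": int(skipped),
    }
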