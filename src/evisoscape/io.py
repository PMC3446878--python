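"""File formats and run configuration.

CSV is the tabular interchange format (stations, observations, site
constants, EVI series, reports).  Rasters travel as ESRI ASCII grids
(plain-text, GDAL-readable) with a ``.prj`` sidecar carrying the CRS label;
a multi-band EVI stack is a directory of per-composite grids plus a JSON
manifest holding the composite dates, CRS and affine transform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .model import FitConfig, IsoModelParams, IsoObservation
from .spatial import IsoscapeGrid, Station, NODATA
from .timeseries import EviSeries, SmoothingConfig

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_evi_series",
    "write_evi_series",
    "read_stations",
    "write_stations",
    "read_station_obs",
    "write_station_obs",
    "read_constants",
    "write_constants",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_evi_stack",
    "read_evi_raster_stack",
    "write_isoscape",
    "read_isoscape",
]


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _row_err(path, i, msg):
    # +2: header line and 1-based numbering
    return SchemaError(f"{path}, row {i + 2}: {msg}")


# ---------------------------------------------------------------- tabular

def read_evi_series(path) -> dict:
    """Read per-site EVI series from CSV (site_id, date, evi)."""
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "date", "evi"], path)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable date ({exc})") from None
    out = {}
    for site, sub in df.groupby("site_id", sort=True):
        sub = sub.sort_values("date")
        out[str(site)] = EviSeries(str(site), pd.DatetimeIndex(sub["date"]),
                                   sub["evi"].to_numpy(dtype=float))
    return out


def write_evi_series(path, series_by_site: dict, smoothed: bool = False):
    rows = []
    for site in sorted(series_by_site):
        s = series_by_site[site]
        v = s.smoothed if smoothed else s.values
        for t, x in zip(s.times, v):
            rows.append({"site_id": site, "date": t.date().isoformat(),
                         "evi": x})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_stations(path) -> list:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "lon", "lat", "elevation"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(Station(str(row["site_id"]), float(row["lon"]),
                               float(row["lat"]), float(row["elevation"]),
                               row.get("land_cover")))
        except (ValueError, TypeError) as exc:
            raise _row_err(path, i, str(exc)) from None
    return out


def write_stations(path, stations):
    pd.DataFrame([{
        "site_id": s.site_id, "lon": s.lon, "lat": s.lat,
        "elevation": s.elevation,
    } for s in stations]).to_csv(path, index=False)


def read_station_obs(path) -> list:
    """Read precipitation-sample observations from CSV.

    Required columns: site_id, start, end, d18o; optional: x, dD,
    precip_amount.  Dates are ISO-8601; a missing x column yields NaN
    covariates to be filled from an EVI series later.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "start", "end", "d18o"], path)
    out = []
    for i, row in df.iterrows():
        try:
            start = pd.Timestamp(row["start"])
            end = pd.Timestamp(row["end"])
            x = float(row["x"]) if "x" in df.columns else 0.0
            d18o = float(row["d18o"])
            if not np.isfinite(d18o):
                raise ValueError(f"non-finite d18o {row['d18o']!r}")
            dD = float(row["dD"]) if "dD" in df.columns \
                and np.isfinite(row["dD"]) else None
            amt = float(row["precip_amount"]) if "precip_amount" in df.columns \
                and np.isfinite(row["precip_amount"]) else None
            out.append(IsoObservation(str(row["site_id"]), (start, end),
                                      x, d18o, dD, amt))
        except (ValueError, TypeError) as exc:
            raise _row_err(path, i, str(exc)) from None
    return out


def write_station_obs(path, obs):
    rows = []
    for o in obs:
        rows.append({
            "site_id": o.site_id,
            "start": o.interval[0].isoformat(),
            "end": o.interval[1].isoformat(),
            "x": o.x, "d18o": o.d18o,
            "dD": "" if o.dD is None else o.dD,
            "precip_amount": "" if o.precip_amount is None else o.precip_amount,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_constants(path) -> dict:
    """Read the site-constants table (station, a, b, c, d, e [, model_ievi])."""
    df = pd.read_csv(path)
    _require_columns(df, ["station", "a", "b", "c", "d", "e"], path)
    out = {}
    for i, row in df.iterrows():
        try:
            p = IsoModelParams(*(float(row[k]) for k in "abcde"))
            extra = float(row["model_ievi"]) if "model_ievi" in df.columns \
                and np.isfinite(row["model_ievi"]) else None
            out[str(row["station"])] = (p, extra)
        except (ValueError, TypeError) as exc:
            raise _row_err(path, i, str(exc)) from None
    return out


def write_constants(path, constants: dict):
    """Write station constants; values are (params, model_ievi|None) or params."""
    rows = []
    for station in constants:
        val = constants[station]
        p, ievi = val if isinstance(val, tuple) else (val, None)
        row = {"station": station, "a": p.a, "b": p.b, "c": p.c,
               "d": p.d, "e": p.e}
        if ievi is not None:
            row["model_ievi"] = ievi
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- rasters

def write_ascii_grid(path, values: np.ndarray, transform, crs: str,
                     nodata: float = NODATA):
    """Write a (y, x) array as an ESRI ASCII grid with a .prj sidecar."""
    path = Path(path)
    ny, nx = values.shape
    a, b, c, d, e, f = transform
    if b != 0 or d != 0 or abs(abs(a) - abs(e)) > 1e-9:
        raise ValueError("ASCII grid requires north-up square cells")
    cell = abs(a)
    xll = c
    yll = f + e * ny  # e is negative (north-up)
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\nxllcorner {xll!r}\n"
                 f"yllcorner {yll!r}\ncellsize {cell!r}\n"
                 f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    path.with_suffix(".prj").write_text(crs + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (values, transform, crs, nodata)."""
    path = Path(path)
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nx, ny = int(hdr["ncols"]), int(hdr["nrows"])
    vals = vals.reshape(ny, nx)
    cell = hdr["cellsize"]
    nodata = hdr.get("nodata_value", NODATA)
    transform = (cell, 0.0, hdr["xllcorner"], 0.0, -cell,
                 hdr["yllcorner"] + cell * ny)
    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise SchemaError(f"{path}: missing georeferencing sidecar {prj.name}")
    crs = prj.read_text().strip()
    vals = np.where(vals == nodata, np.nan, vals)
    return vals, transform, crs, nodata


def _grid_coords(transform, ny, nx):
    a, _, c, _, e, f = transform
    x = c + a * (np.arange(nx) + 0.5)
    y = f + e * (np.arange(ny) + 0.5)
    return y, x


def write_evi_stack(directory, stack: xr.DataArray):
    """Write a (time, y, x) EVI stack as per-band ASCII grids + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    transform = tuple(stack.attrs["transform"])
    crs = stack.attrs["crs"]
    times = pd.DatetimeIndex(pd.to_datetime(stack["time"].values))
    bands = []
    for k, t in enumerate(times):
        name = f"band_{k:03d}.asc"
        write_ascii_grid(directory / name, np.asarray(stack.values[k]),
                         transform, crs)
        bands.append({"file": name, "date": t.isoformat()})
    (directory / "manifest.json").write_text(json.dumps({
        "crs": crs, "transform": list(transform), "bands": bands,
    }, indent=1))


def read_evi_raster_stack(directory) -> xr.DataArray:
    """Read an EVI stack directory back into a (time, y, x) DataArray."""
    directory = Path(directory)
    manifest = directory / "manifest.json"
    if not manifest.exists():
        raise SchemaError(f"{directory}: missing manifest.json")
    meta = json.loads(manifest.read_text())
    if "transform" not in meta or "crs" not in meta:
        raise SchemaError(f"{manifest}: missing georeferencing")
    if not meta.get("bands") or any("date" not in b for b in meta["bands"]):
        raise SchemaError(f"{manifest}: bands without composite dates")
    arrs, times = [], []
    for band in meta["bands"]:
        vals, transform, crs, _ = read_ascii_grid(directory / band["file"])
        if not np.allclose(transform, meta["transform"]) or crs != meta["crs"]:
            raise SchemaError(
                f"{band['file']}: CRS/transform mismatch with manifest"
            )
        arrs.append(vals)
        times.append(pd.Timestamp(band["date"]))
    vals = np.stack(arrs)
    ny, nx = vals.shape[1:]
    y, x = _grid_coords(meta["transform"], ny, nx)
    return xr.DataArray(
        vals, dims=("time", "y", "x"),
        coords={"time": pd.DatetimeIndex(times), "y": y, "x": x},
        attrs={"transform": tuple(meta["transform"]), "crs": meta["crs"]},
    )


def write_isoscape(path, grid: IsoscapeGrid):
    """Write an isoscape raster (ASCII grid + .prj + .json time-step meta)."""
    path = Path(path)
    write_ascii_grid(path, np.asarray(grid.data.values, dtype=np.float32),
                     grid.transform, grid.crs, grid.nodata)
    meta = {"time_step": [t.isoformat() for t in grid.time_step],
            "units": "permil"}
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_isoscape(path) -> IsoscapeGrid:
    path = Path(path)
    vals, transform, crs, nodata = read_ascii_grid(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ts = tuple(pd.Timestamp(t) for t in meta.get("time_step", [])) or \
        (pd.NaT, pd.NaT)
    ny, nx = vals.shape
    y, x = _grid_coords(transform, ny, nx)
    da = xr.DataArray(vals, dims=("y", "x"), coords={"y": y, "x": x},
                      attrs={"units": "permil", "nodata": nodata})
    return IsoscapeGrid(da, crs, transform, ts, nodata)


# ---------------------------------------------------------------- config

_TUPLE_FIELDS = {"a_floor_grid", "d_min_grid", "d_max_grid",
                 "cloud_spike_range", "elevation_range"}


def _from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {', '.join(sorted(unknown))}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run; round-trips via YAML."""

    seed: int = 0
    season_threshold: float = 0.167
    start_fraction: float = 1.0 / 6.0
    exclusion_threshold: float = 3.0
    crs: str = "EPSG:32651"
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    fit: FitConfig = field(default_factory=FitConfig)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)

        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (tuple, list)):
                return [clean(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return yaml.safe_dump(clean(d), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise SchemaError("config: expected a mapping")
        sm = data.pop("smoothing", None)
        ft = data.pop("fit", None)
        cfg = _from_dict(cls, data | {}, "config")
        if sm is not None:
            cfg = dataclasses.replace(
                cfg, smoothing=_from_dict(SmoothingConfig, sm, "smoothing"))
        if ft is not None:
            cfg = dataclasses.replace(
                cfg, fit=_from_dict(FitConfig, ft, "fit"))
        return cfg
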