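"""Cross-validated predictability of the iEVI–δ¹⁸O functions.

The study design: fit each site's function on one growing season (the
four-pair training design, or all in-season observations), transfer
it to the remaining seasons by rescaling the kink location b with the ratio
of complete-growing-season iEVIs, predict every sampling interval, and
score predictions against observations with Pearson's r at 16-day,
monthly, seasonal and annual aggregation.  Because r is invariant to
affine rescaling of the predictions, these scores measure covariation, not
absolute bias — the end-to-end identity test on noise-free data is the
complementary absolute check.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    FitConfig,
    UnderdeterminedError,
    fit_iso_model,
    predict_d18o,
    rescale_b,
    select_training_pairs,
)
from .timeseries import compute_ievi, ievi_covariates

__all__ = [
    "PredictabilityReport",
    "UndefinedCorrelationError",
    "pearson_predictability",
    "exclude_extrema",
    "cross_validate_network",
    "site_predictability",
    "variability_correlation",
    "meteoric_water_line",
]

logger = logging.getLogger(__name__)

SCALES = ("16-day", "monthly", "seasonal", "annual")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (too few pairs or zero variance)."""


@dataclass
class PredictabilityReport:
    """Predictability at one aggregation scale."""

    scale: str
    per_site_r: dict  # site_id -> r (NaN where not computable)
    pooled_r: float
    mean_r: float  # mean of per-site r over sites with a defined r
    se_r: float
    n_pairs: int
    n_excluded: int
    skipped_sites: dict = field(default_factory=dict)  # site_id -> reason


def pearson_predictability(pred, obs) -> float:
    """Pearson product-moment correlation of predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    if len(pred) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 paired values, got {len(pred)}"
        )
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise UndefinedCorrelationError("zero variance on one side")
    return float(stats.pearsonr(pred, obs).statistic)


def exclude_extrema(df: pd.DataFrame, season_col: str = "season",
                    value_col: str = "d18o", threshold: float = 3.0):
    """Drop at most one extreme observation per season.

    Within each season, the observation with the largest absolute robust
    z-score of δ¹⁸O (median / scaled MAD) is removed — and only if that
    z-score exceeds ``threshold``.  Seasons with zero spread are left
    unchanged.  Returns (filtered frame, exclusion log frame).
    """
    keep = np.ones(len(df), dtype=bool)
    log = []
    positions = {label: np.flatnonzero((df[season_col] == label).to_numpy())
                 for label in df[season_col].unique()}
    for label, pos in positions.items():
        v = df[value_col].to_numpy()[pos]
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad == 0:
            continue
        z = np.abs(v - med) / mad
        i = int(np.argmax(z))
        if z[i] > threshold:
            keep[pos[i]] = False
            log.append({
                "season": label,
                "index": df.index[pos[i]],
                "value": float(v[i]),
                "z": float(z[i]),
            })
            logger.info("excluded extremum in season %s: %.2f (|z|=%.1f)",
                        label, v[i], z[i])
    return df[keep], pd.DataFrame(log, columns=["season", "index", "value", "z"])


def _predict_site(record, train_label, training, fit_cfg, start_fraction):
    """Fit on the training season and predict all other seasons of a site.

    Returns a DataFrame (site, season, date, pred, obs) for target seasons.
    """
    train_obs = record.obs_by_season.get(train_label, [])
    season = record.seasons[train_label]
    block = record.blocks[train_label]
    if training == "four-pair":
        picked = select_training_pairs(train_obs, season)
        fit_cfg = dataclasses.replace(fit_cfg, allow_underdetermined=True)
    elif training == "all":
        picked = list(train_obs)
    else:
        raise ValueError(f"unknown training mode {training!r}")
    mids = [o.midpoint for o in picked]
    x = ievi_covariates(block, season, mids, start_fraction)
    refit = [dataclasses.replace(o, x=float(xi)) for o, xi in zip(picked, x)]
    fit = fit_iso_model(refit, fit_cfg)
    model_ievi = compute_ievi(block, season, start_fraction=0.0)

    rows = []
    for label, obs in record.obs_by_season.items():
        if label == train_label:
            continue
        target_season = record.seasons[label]
        target_block = record.blocks[label]
        target_ievi = compute_ievi(target_block, target_season,
                                   start_fraction=0.0)
        b_new = rescale_b(fit.params.b, model_ievi, target_ievi)
        params = dataclasses.replace(fit.params, b=b_new)
        mids = [o.midpoint for o in obs]
        xt = ievi_covariates(target_block, target_season, mids, start_fraction)
        pred = predict_d18o(params, xt)
        for o, p in zip(obs, np.atleast_1d(pred)):
            rows.append({
                "site": record.station.site_id, "season": label,
                "date": o.midpoint, "pred": float(p), "obs": o.d18o,
            })
    return pd.DataFrame(rows)


def _aggregate(df: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "16-day":
        return df
    d = df.assign(year=df["date"].dt.year, month=df["date"].dt.month)
    keys = {
        "monthly": ["site", "year", "month"],
        "seasonal": ["site", "season"],
        "annual": ["site", "year"],
    }[scale]
    return d.groupby(keys, sort=True)[["pred", "obs"]].mean().reset_index()


def _safe_r(pred, obs):
    try:
        return pearson_predictability(pred, obs)
    except UndefinedCorrelationError:
        return float("nan")


def cross_validate_network(dataset, train_label=None, training: str = "four-pair",
                           fit_cfg: FitConfig = FitConfig(),
                           scales=SCALES, exclusion_threshold: float = 3.0,
                           start_fraction: float = 1.0 / 6.0):
    """Leave-future-seasons-out predictability over a station network.

    ``dataset`` is a :class:`~evisoscape.synthetic.NetworkDataset`-like
    object (sites with per-season blocks, growing seasons and
    observations).  Per site: fit on ``train_label`` (default: earliest
    season), transfer b to each other season, predict all its sampling
    intervals; extrema (at most one per season, robust z > threshold) are
    excluded before correlation.  Returns a dict scale ->
    :class:`PredictabilityReport`; sites without enough training pairs are
    skipped with a logged reason.
    """
    if train_label is None:
        train_label = dataset.season_labels[0]
    frames, skipped = [], {}
    for record in dataset.sites:
        try:
            frames.append(_predict_site(record, train_label, training,
                                        fit_cfg, start_fraction))
        except (ValueError, UnderdeterminedError) as exc:
            reason = f"insufficient training pairs ({exc})" \
                if "insufficient" in str(exc) or "observations" in str(exc) \
                else str(exc)
            skipped[record.station.site_id] = reason
            logger.warning("site %s skipped: %s", record.station.site_id,
                           reason)
    if not frames:
        raise ValueError("no site could be cross-validated")
    df = pd.concat(frames, ignore_index=True)
    df["season_key"] = df["site"] + "/" + df["season"].astype(str)
    kept, log = exclude_extrema(df, "season_key", "obs", exclusion_threshold)
    n_excluded = len(log)

    reports = {}
    for scale in scales:
        agg = _aggregate(kept, scale)
        pooled = _safe_r(agg["pred"], agg["obs"])
        per_site = {}
        for site, sub in agg.groupby("site"):
            per_site[site] = _safe_r(sub["pred"], sub["obs"])
        rs = np.array([r for r in per_site.values() if np.isfinite(r)])
        mean_r = float(np.mean(rs)) if len(rs) else float("nan")
        se_r = float(np.std(rs, ddof=1) / np.sqrt(len(rs))) \
            if len(rs) > 1 else 0.0
        reports[scale] = PredictabilityReport(
            scale, per_site, pooled, mean_r, se_r, len(agg), n_excluded,
            skipped,
        )
    return reports


def site_predictability(record, train_label, training: str = "all",
                        fit_cfg: FitConfig = FitConfig(),
                        start_fraction: float = 1.0 / 6.0) -> float:
    """Pooled 16-day r for a single site's fit/predict cycle."""
    df = _predict_site(record, train_label, training, fit_cfg, start_fraction)
    return _safe_r(df["pred"], df["obs"])


def variability_correlation(evi_by_site: dict, d18o_by_site: dict) -> float:
    """Correlation of per-site temporal variability of EVI and δ¹⁸O.

    Per site, variability is the standard deviation of the multi-year EVI
    series and of the δ¹⁸O series; the statistic is Pearson's r of the two
    across sites.
    """
    sites = sorted(set(evi_by_site) & set(d18o_by_site))
    if len(sites) < 3:
        raise ValueError(f"need >= 3 sites, got {len(sites)}")
    evi_sd = [float(np.std(np.asarray(evi_by_site[s], dtype=float), ddof=1))
              for s in sites]
    d18o_sd = [float(np.std(np.asarray(d18o_by_site[s], dtype=float), ddof=1))
               for s in sites]
    return pearson_predictability(evi_sd, d18o_sd)


def meteoric_water_line(d18o, dD):
    """Local meteoric water line: OLS of δD on δ¹⁸O.

    Returns (slope, intercept, residuals).  Data on the global line
    δD = 8·δ¹⁸O + 10 give slope 8, intercept 10 and zero residuals.
    """
    d18o = np.asarray(d18o, dtype=float)
    dD = np.asarray(dD, dtype=float)
    if len(d18o) != len(dD):
        raise ValueError("d18o and dD must have equal length")
    if len(d18o) < 3:
        raise ValueError(f"need >= 3 paired values, got {len(d18o)}")
    if np.std(d18o) == 0:
        raise ValueError("degenerate: zero variance in d18o")
    res = stats.linregress(d18o, dD)
    resid = dD - (res.slope * d18o + res.intercept)
    return float(res.slope), float(res.intercept), resid
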