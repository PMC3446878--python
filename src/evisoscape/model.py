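"""The iEVI–δ¹⁸O site function and its constrained multi-start fit.

A site's precipitation δ¹⁸O over the growing season is modelled as a
function of the cumulative growing-season integrated EVI x:

    δ¹⁸O(x) = −a·(|x − b| + c)² + d·x − e

with five site constants: a > 0 (curvature, ‰ per iEVI²), b (kink location,
iEVI units, where δ¹⁸O peaks mid-season), c < 0 (kink offset, iEVI units),
d (linear slope, ‰ per iEVI) and e > 0 (offset, ‰).  The fit minimises the
root of the summed squared residuals (root-SSE, not divided by n) under box
constraints, restarting a bound-constrained least-squares solver from
seeded random points inside each cell of a 7×3×3 grid of initial bounds on
(a-floor, d-min, d-max) — 63 cells — and keeping the lowest root-SSE found.

For transfer to another growing season only the kink location moves: b is
rescaled by the ratio of the complete-growing-season iEVI of the prediction
season to that of the model season.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "IsoModelParams",
    "IsoObservation",
    "FitConfig",
    "FitResult",
    "GLOBAL_BOUNDS",
    "UnderdeterminedError",
    "DegenerateDesignError",
    "predict_d18o",
    "root_sse_objective",
    "fit_iso_model",
    "rescale_b",
    "select_training_pairs",
]

#: Global feasibility box for the five constants: a > 0.0005, 20 < b < 300,
#: −200 < c < 0, −0.4 < d < 0.4, 0 < e < 100.  The upper bound on a is an
#: implementation choice (the curvature of real sites is O(0.003)).
GLOBAL_BOUNDS = {
    "a": (0.0005, 0.01),
    "b": (20.0, 300.0),
    "c": (-200.0, 0.0),
    "d": (-0.4, 0.4),
    "e": (0.0, 100.0),
}


class UnderdeterminedError(ValueError):
    """Fewer observations than free parameters."""


class DegenerateDesignError(ValueError):
    """All covariate values identical — constants not identifiable."""


@dataclass(frozen=True)
class IsoModelParams:
    """The five site constants of the iEVI–δ¹⁸O function."""

    a: float
    b: float
    c: float
    d: float
    e: float

    def validate(self, bounds: dict = GLOBAL_BOUNDS) -> "IsoModelParams":
        for name in "abcde":
            lo, hi = bounds[name]
            v = getattr(self, name)
            if not (np.isfinite(v) and lo <= v <= hi):
                raise ValueError(
                    f"constant {name}={v} outside feasible range ({lo}, {hi})"
                )
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e])

    @classmethod
    def from_array(cls, p) -> "IsoModelParams":
        return cls(*map(float, p))


@dataclass(frozen=True)
class IsoObservation:
    """One precipitation-sampling interval with its iEVI covariate."""

    site_id: str
    interval: tuple  # (start, end) timestamps
    x: float  # cumulative in-season iEVI at the interval midpoint
    d18o: float  # permil VSMOW
    dD: float | None = None
    precip_amount: float | None = None

    def __post_init__(self):
        a, b = pd.Timestamp(self.interval[0]), pd.Timestamp(self.interval[1])
        if not a < b:
            raise ValueError(f"interval {a}..{b} ill-ordered")
        object.__setattr__(self, "interval", (a, b))
        if not np.isfinite(self.x):
            raise ValueError("covariate x must be finite")
        if not np.isfinite(self.d18o):
            raise ValueError("d18o must be finite")

    @property
    def midpoint(self) -> pd.Timestamp:
        a, b = self.interval
        return a + (b - a) / 2


@dataclass(frozen=True)
class FitConfig:
    """Multi-start fit settings.

    63 initial-bound cells (7 curvature floors × 3 slope minima × 3 slope
    maxima), ``restarts`` seeded random starting points per cell.
    """

    restarts: int = 30
    a_floor_grid: tuple = tuple(np.round(np.arange(0.0005, 0.00351, 0.0005), 5))
    d_min_grid: tuple = (-0.1, -0.2, -0.3)
    d_max_grid: tuple = (0.1, 0.2, 0.3)
    a_upper: float = 0.01
    rng_seed: int = 0
    xtol: float = 1e-12
    allow_underdetermined: bool = False
    #: stop the multi-start search once the objective is numerically zero —
    #: no later restart can improve on it
    early_stop_sse: float = 1e-10

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not (self.a_floor_grid and self.d_min_grid and self.d_max_grid):
            raise ValueError("initial-bound grids must be non-empty")

    def cells(self):
        return list(itertools.product(self.a_floor_grid, self.d_min_grid,
                                      self.d_max_grid))


@dataclass(frozen=True)
class FitResult:
    params: IsoModelParams
    root_sse: float  # permil
    r_squared: float
    n_obs: int
    winning_cell: tuple  # (a_floor, d_min, d_max)
    converged: bool


def predict_d18o(params: IsoModelParams, x):
    """δ¹⁸O (‰) at covariate x: −a·(|x−b|+c)² + d·x − e.

    Continuous everywhere, differentiable except at the kink x = b; the
    non-linear term is symmetric about b.
    """
    x = np.asarray(x, dtype=float)
    y = -params.a * (np.abs(x - params.b) + params.c) ** 2 + params.d * x - params.e
    return float(y) if y.ndim == 0 else y


def root_sse_objective(params: IsoModelParams, obs) -> float:
    """Root of the summed squared residuals (‰) — the fit objective.

    Not divided by n: the objective is sqrt(SSE), not an RMS error.
    """
    x, y = _design(obs)
    r = predict_d18o(params, x) - y
    return float(np.sqrt(np.sum(r * r)))


def _design(obs):
    if len(obs) == 0:
        raise ValueError("no observations")
    x = np.array([o.x for o in obs], dtype=float)
    y = np.array([o.d18o for o in obs], dtype=float)
    return x, y


def _residuals(p, x, y):
    a, b, c, d, e = p
    return -a * (np.abs(x - b) + c) ** 2 + d * x - e - y


def _jacobian(p, x, y):
    a, b, c, d, e = p
    u = np.abs(x - b) + c
    s = np.sign(x - b)
    J = np.empty((len(x), 5))
    J[:, 0] = -(u * u)
    J[:, 1] = 2.0 * a * u * s
    J[:, 2] = -2.0 * a * u
    J[:, 3] = x
    J[:, 4] = -1.0
    return J


def fit_iso_model(obs, cfg: FitConfig = FitConfig()) -> FitResult:
    """Constrained multi-start least-squares fit of the five constants.

    For each of the 63 (a_floor, d_min, d_max) initial-bound cells, run
    ``cfg.restarts`` bound-constrained trust-region least-squares solves
    from uniform-random starting points inside the cell's box and keep the
    lowest root-SSE; the global best across cells is returned with its r²
    (squared Pearson correlation of predictions and observations).
    Deterministic given ``cfg.rng_seed``; the per-cell random starting
    points form a fixed sequence, so the best objective is non-increasing
    in the number of restarts.
    """
    x, y = _design(obs)
    n = len(x)
    if n < 5 and not cfg.allow_underdetermined:
        raise UnderdeterminedError(
            f"{n} observations for 5 free parameters; need >= 5"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all covariate values identical")

    eps = 1e-9
    best = None
    any_converged = False
    for cell_idx, (a_floor, d_min, d_max) in enumerate(cfg.cells()):
        lo = np.array([a_floor, GLOBAL_BOUNDS["b"][0], GLOBAL_BOUNDS["c"][0],
                       max(d_min, GLOBAL_BOUNDS["d"][0]), GLOBAL_BOUNDS["e"][0]])
        hi = np.array([cfg.a_upper, GLOBAL_BOUNDS["b"][1], GLOBAL_BOUNDS["c"][1],
                       min(d_max, GLOBAL_BOUNDS["d"][1]), GLOBAL_BOUNDS["e"][1]])
        lo = lo + eps * np.maximum(1.0, np.abs(lo))
        hi = hi - eps * np.maximum(1.0, np.abs(hi))
        rng = np.random.default_rng([cfg.rng_seed, cell_idx])
        for _ in range(cfg.restarts):
            p0 = rng.uniform(lo, hi)
            try:
                sol = least_squares(
                    _residuals, p0, jac=_jacobian, bounds=(lo, hi),
                    method="trf", args=(x, y),
                    xtol=cfg.xtol, ftol=1e-14, gtol=1e-14, max_nfev=400,
                )
            except Exception:  # pragma: no cover - solver pathologies
                continue
            obj = float(np.sqrt(2.0 * sol.cost))
            any_converged = any_converged or bool(sol.success)
            if best is None or obj < best[0]:
                best = (obj, sol.x, (a_floor, d_min, d_max), bool(sol.success))
            if best[0] <= cfg.early_stop_sse:
                break
        if best is not None and best[0] <= cfg.early_stop_sse:
            break
    if best is None:
        raise RuntimeError("no restart produced a solution")
    obj, p, cell, conv = best
    params = IsoModelParams.from_array(p)
    pred = predict_d18o(params, x)
    if np.std(pred) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
        r2 = min(max(r2, 0.0), 1.0)
    else:
        r2 = 0.0
    return FitResult(params, obj, r2, n, cell, conv)


def rescale_b(b_model: float, ievi_model_season: float,
              ievi_pred_season: float) -> float:
    """Transfer the kink location b to another growing season.

    b_predict = b_model · (iEVI of the complete prediction-season /
    iEVI of the complete model-season); all other constants carry over
    unchanged.  Identity when the season iEVIs are equal.
    """
    if not ievi_model_season > 0:
        raise ValueError("model-season iEVI must be positive")
    return b_model * (ievi_pred_season / ievi_model_season)


def select_training_pairs(obs, season, quantiles=(0.0, 0.4, 0.6, 1.0)):
    """Pick the four training observations of a growing season.

    One near the beginning, two near the middle and one near the end:
    the in-season observations whose interval midpoints fall nearest to the
    season-time quantiles (default 0, 0.4, 0.6, 1).  Ties break toward the
    earlier observation; the four picks are distinct.  Returned in
    chronological order.
    """
    start, end = season.start_time, season.end_time
    span = (end - start).value
    cands = [(o, (o.midpoint - start).value / span) for o in obs
             if start <= o.midpoint <= end]
    if len(cands) < len(quantiles):
        raise ValueError(
            f"insufficient training pairs: {len(cands)} in-season "
            f"observations, need {len(quantiles)}"
        )
    chosen: list[int] = []
    for q in quantiles:
        best_i, best_key = None, None
        for i, (o, f) in enumerate(cands):
            if i in chosen:
                continue
            key = (abs(f - q), o.midpoint)
            if best_key is None or key < best_key:
                best_i, best_key = i, key
        chosen.append(best_i)
    picked = [cands[i][0] for i in chosen]
    return sorted(picked, key=lambda o: o.midpoint)
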