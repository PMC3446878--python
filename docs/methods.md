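# Methods

## The model

Precipitation δ¹⁸O at a site is modelled as a function of a single
covariate x, the *cumulative growing-season integrated EVI*:

    δ¹⁸O(x) = −a·(|x − b| + c)² + d·x − e

- **x** (iEVI units = EVI·days): the integral of the smoothed EVI curve
  from the season integration start (one sixth of the way through the
  growing season) up to the observation interval's midpoint. x runs from 0
  at the start of the season to the complete-season iEVI at its end, so it
  is a season-progress coordinate expressed in accumulated plant growth.
- **a** (‰ per iEVI², > 0.0005): curvature. **b** (iEVI units, 20–300):
  the kink, the point of the season where δ¹⁸O is most depleted
  (mid-season / monsoon). **c** (iEVI units, −200–0): offset of the kink
  argument; |x − b| = −c marks the enriched shoulders. **d** (‰ per iEVI,
  |d| < 0.4): linear trend across the season. **e** (‰, 0–100): offset.
- The function is continuous everywhere and differentiable except at
  x = b; the non-linear part is symmetric about b. The derivative jump
  −4ac at the kink is what makes all five constants identifiable when the
  observation design spans b.

The covariate is *cumulative* rather than per-interval: the magnitudes of
the reference kink locations (≈70–130 iEVI units) match complete-season
integrals, not single-interval ones, and the cross-season transfer rule —
b_predict = b_model · (complete-season iEVI of the prediction season /
complete-season iEVI of the model season) — is only meaningful if b lives
on the cumulative scale. Both season integrals use the full season
(integration start fraction 0); consistency between numerator and
denominator is what matters.

## Fitting

The objective is the root of the summed squared residuals (root-SSE, not
divided by n). Fitting runs a bound-constrained trust-region least-squares
solver (scipy `least_squares`, analytic Jacobian) from random starting
points:

- 63 initial-bound cells: curvature floor a_floor ∈ {0.0005 … 0.0035 step
  0.0005} × slope bounds d_min ∈ {−0.1, −0.2, −0.3}, d_max ∈ {0.1, 0.2,
  0.3}; each cell's box is the global box with those faces tightened.
- 30 restarts per cell by default, starting points uniform in the cell's
  box from a per-cell RNG seeded as (rng_seed, cell index). The per-cell
  draws form a fixed sequence, so the best objective is deterministic
  given the seed and non-increasing in the number of restarts.
- The upper bound a ≤ 0.01 closes the box (the curvature has no natural
  upper limit; observed values are O(0.003)). Strict inequalities are
  shrunk to closed intervals by a relative 1e-9 because numerical
  optimizers need closed boxes. Solver tolerances: xtol 1e-12, ftol/gtol
  1e-14.
- **Early stop**: the multi-start search halts once the best root-SSE is
  ≤ 1e-10 — a numerically zero objective cannot be improved by further
  restarts. This matters for underdetermined four-point training fits,
  where the solver otherwise polishes a zero-residual solution manifold
  until its evaluation budget is exhausted.
- Reported r² is the squared Pearson correlation of fitted predictions
  and observations, clipped to [0, 1].
- Fewer than 5 observations raises an underdetermined error by default;
  the four-pair training design opts in explicitly
  (`allow_underdetermined=True`) and accepts that the recovered constants
  are then one of a one-parameter family interpolating the four points.

## EVI preprocessing

- **Smoothing** is a weighted local polynomial fit (degree 2, half-window
  5 points → 11-point windows, truncated asymmetrically at the series
  boundaries, actual day offsets as the regressor so uneven spacing is
  handled). Envelope adaptation: after each of 3 iterations, points below
  the current fit are down-weighted by
  w ← min(w, 1/(1 + (gap/(s·σ))²)) with adaptation strength s = 3 and σ
  the residual standard deviation. Down-weighting is monotone (weights
  never recover), so total weight mass is non-increasing across
  iterations and weights stay in (0, 1]. The kernel itself is a design
  choice — the exact TIMESAT kernel is not publicly documented — and is the one
  place the adaptation-strength parameter enters.
- Missing composites are linearly gap-filled before smoothing and
  flagged; more than 3 consecutive missing values (or missing boundary
  values) is a hard error.
- **Season detection** on the smoothed curve: base level = mean of the
  pre-peak and post-peak minima; amplitude = seasonal max − base; the
  season starts/ends where the curve crosses base + 0.167·amplitude on
  the rising/falling limb, linearly interpolated between composites. The
  0.167 threshold is an *amplitude* fraction (the TIMESAT convention for
  season limits); the "one sixth of the growing season" integration start
  is an independent *time* fraction. Both are separate settings. A
  seasonal amplitude below `min_amplitude` (default 0.01 EVI) raises
  "no season detected".
- **Integration** is trapezoidal on the piecewise-linear smoothed curve
  with exact partial intervals at both ends, in days. iEVI is additive
  over partitions and linear in the curve.

## Spatial extension

Off-site prediction combines exactly the two relationships the site
network supports: the nearest anchor's (in elevation) iEVI–δ¹⁸O function
with b rescaled to the target pixel's complete-season iEVI, plus the
residual of the linear δ¹⁸O–elevation (lapse) relation between pixel and
anchor elevation. The lapse relation is refit per time step by default.
An alternative scheme (interpolating the five constants in elevation) was
considered and not implemented: the constants are not individually smooth
in elevation (b and c trade off along the fitted manifold), whereas
predictions and the lapse relation are.

Rasters are xarray DataArrays carrying a rasterio-style affine transform
and a CRS label; the raster path is literally the scalar pipeline applied
per pixel, and a test asserts pixelwise agreement within 1e-9 ‰ on a
20×20 scene. On-disk format is the ESRI ASCII grid (plain text,
GDAL-readable) with a `.prj` sidecar; EVI stacks are directories of grids
with a JSON manifest of composite dates. Ring sensitivity (focal vs
neighboring pixels) uses Chebyshev rings at 1 and 2 cells (250 m and
500 m: 8 and 16 pixels per site), pooling Δr = r(ring) − r(focal) across
sites with a one-sample two-sided t test.

## Cross-validation harness

Per site: select training observations in the training season (default:
the four whose interval midpoints are nearest the season-time quantiles
{0, 0.4, 0.6, 1}, ties to the earlier observation — "two in the middle"
is operationalised as the 0.4/0.6 quantiles; `training="all"` uses every
in-season observation instead), fit, rescale b to each target season,
predict all its intervals. Aggregation: "16-day" is the native sampling
interval; "monthly" averages predictions and observations within calendar
months; "seasonal" and "annual" average within season blocks and years.
Pearson r is reported pooled across sites and per site (mean ± SE across
sites). Because r is affine-invariant, a b-rescaling error that shifted
all predictions by a constant would not show up in r; the noise-free
end-to-end identity test is the absolute check.

**Extrema exclusion**: within each season, at most the single observation
with the largest absolute robust z-score ((value − median)/(1.4826·MAD))
is removed, and only if that score exceeds 3; zero-spread seasons are
never touched and every removal is logged. The cap of one removal per
season is structural.

## The synthetic study system

The generator emulates a 13-station elevation transect (91–2876 m
a.s.l.) sampled approximately monthly over three growing seasons, with
per-site constants taken from a stored 13-row reference table (site k
gets row k; other network sizes interpolate each constant against site
rank, which keeps values inside the columnwise envelope).

- EVI curves are double logistics: base 0.12, amplitude falling from 0.55
  to 0.30 with elevation, green-up/senescence shifting to give shorter,
  later seasons uphill; Gaussian noise (sd 0.015) plus negative-only
  cloud spikes (probability 0.08, depth U(0.15, 0.35)) motivate the
  upper-envelope smoothing.
- The seasonal cycle has a period of 368 days so that 23 16-day
  composites tile it exactly. Real 16-day products re-anchor composites
  each calendar year (and leap years shift the spacing); the idealisation
  buys exact repeatability of noise-free seasons across years, which the
  end-to-end identity test requires. Season blocks are labelled by their
  starting calendar year.
- δ¹⁸O observations are the site function evaluated at the
  pipeline-computed covariate, plus Gaussian noise (sd 0.5 ‰) and, with
  probability 0.08, a −6 ‰ depletion outlier (the tropical-cyclone
  heavy-rain analog; depletion-only by design).
- Raster scenes place the same elevation mapping on a diagonal DEM ramp,
  so seasonal amplitude is monotone in elevation by construction.
- All generators are pure functions of (config, seed); one padding season
  on each side of the simulated span ensures interior seasons are
  smoothed with full windows.

What passing tests on this system do **not** show: real MODIS EVI has QA
artifacts, snow, multi-modal seasons and calendar re-anchoring; real
isotope data have amount effects, moisture-source shifts and multi-permil
event-scale variability. The synthetic system validates the machinery and
its self-consistency, not field predictability.

## Problem sizes and observed behaviour

The test suite and the acceptance script size their simulations for a
single CPU: full 63×30 multi-start recoveries for two sites (24
observations each), a 13-site noise-free closure at 3 restarts per cell,
20-replicate stochastic runs at 2 restarts per cell, and 20×20 raster
scenes. On the noise-free closure the pooled r is 1 to machine precision
at all four aggregation scales.

One documented negative result: with 0.5 ‰ observation noise on this
study system, pooled annual r sits slightly *below* pooled 16-day r
(mean difference ≈ −0.01 over 20 replicates). Aggregation averages noise,
but it also collapses signal: the within-season δ¹⁸O swing implied by the
reference constants is ~16 ‰, while the between-site spread of seasonal
means from those same constants is only ~1.5 ‰, so annual aggregation
removes more signal variance than noise variance whenever event-scale
noise is small. Annual aggregation overtakes event-scale correlation only
when unexplained event-scale variability is large (multi-permil, as in
real monsoon data) — the regime the 0.5 ‰ synthetic condition explicitly
excludes. The corresponding acceptance test states the expected ordering
and fails honestly on this system.

## Known limitations

- Single-season (unimodal) growing seasons only; no multi-season
  handling, no QA-flag decoding, no snow masking.
- The four-pair training design is underdetermined for a five-constant
  model; recovered constants are then design-dependent even noise-free
  (predictions on the sampled branch are not).
- No geostatistical interpolation, latitude/continental effects, or
  amount-weighting of observations.
- The lapse relation is linear in elevation; inversions or coastal
  effects are not representable.
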