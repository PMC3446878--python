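# evisoscape

Fine-scale prediction of precipitation δ¹⁸O from vegetation-index time
series.

## The problem

The spatial pattern of stable water isotopes in precipitation (the water
*isoscape*) is a workhorse tracer in hydrology, paleoclimatology, ecology
and forensics, but station networks measuring δ¹⁸O are sparse and
discontinuous. Satellite vegetation indices, by contrast, are global,
continuous since 2000, and cheap: the MODIS Enhanced Vegetation Index (EVI)
comes as 16-day composites on a 250 m grid. Because plant growth and
precipitation isotopes respond to the same climatic and topographic
drivers, the growing-season integrated EVI (iEVI) carries enough
information to predict precipitation δ¹⁸O at the regional scale — at far
finer spatial and temporal resolution than hydrological-cycle isoscape
models.

`evisoscape` implements that pipeline for users who have (or simulate)
per-site 16-day EVI series and interval-sampled precipitation δ¹⁸O:

1. **Upper-envelope Savitzky–Golay smoothing** of the EVI series
   (TIMESAT-style: iteratively down-weight points below the fit, since
   cloud contamination biases EVI low);
2. **growing-season delimitation** at a threshold fraction (default 0.167)
   of the seasonal amplitude, and **iEVI** integration from one sixth of
   the season to its end;
3. the site-level **iEVI–δ¹⁸O function**

   δ¹⁸O(x) = −a·(|x − b| + c)² + d·x − e

   with five site constants fitted by **constrained multi-start least
   squares** (a 7×3×3 grid of initial bounds on the curvature floor and
   slope range — 63 cells — with 30 seeded random restarts each,
   minimising the root of the summed squared residuals subject to
   a > 0.0005, 20 < b < 300, −200 < c < 0, −0.4 < d < 0.4, 0 < e < 100);
4. **cross-season transfer**: b_predict = b_model · (iEVI of the complete
   prediction season / iEVI of the complete model season), all other
   constants unchanged;
5. **elevation-gradient interpolation** (the linear δ¹⁸O lapse relation)
   and **250 m isoscape rasterisation**;
6. a **cross-validation harness** (four training pairs per
   season, Pearson r at 16-day / monthly / seasonal / annual scales,
   robust-z extrema exclusion capped at one removal per season) and a
   **synthetic-data generator** that builds model-consistent virtual
   station networks and raster scenes, so the whole pipeline is testable
   without any downloads.

## Worked example

Recover a site function from noise-free observations and close the full
pipeline end-to-end:

```python
import numpy as np, pandas as pd
from evisoscape import (IsoModelParams, FitConfig, fit_iso_model,
                        predict_d18o, REFERENCE_CONSTANTS)
from evisoscape.model import IsoObservation
from evisoscape.synthetic import SimConfig, make_network_dataset
from evisoscape.validation import cross_validate_network

truth = IsoModelParams(*REFERENCE_CONSTANTS["s1"])
x = np.linspace(30, 200, 24)
t0 = pd.Timestamp("2007-04-01")
obs = [IsoObservation("s1", (t0 + pd.Timedelta(days=10*i),
                             t0 + pd.Timedelta(days=10*i+5)), xi, yi)
       for i, (xi, yi) in enumerate(zip(x, predict_d18o(truth, x)))]
fit = fit_iso_model(obs, FitConfig(restarts=30, rng_seed=1))
print("fitted:", fit.params)
print("root_sse = %.2e   r^2 = %.6f" % (fit.root_sse, fit.r_squared))
print("d18O at the kink: %.2f permil" % predict_d18o(fit.params, fit.params.b))

ds = make_network_dataset(SimConfig().quiet())          # 13 sites, noise off
reps = cross_validate_network(ds, training="all",
                              fit_cfg=FitConfig(restarts=3, rng_seed=0))
for scale, rep in reps.items():
    print(f"{scale:8s} pooled r = {rep.pooled_r:.6f}")
```

prints

```
fitted: IsoModelParams(a=0.003001, b=110.655, c=-74.069, d=-0.0039299999999999995, e=2.66119)
root_sse = 6.28e-16   r^2 = 1.000000
d18O at the kink: -19.56 permil
16-day   pooled r = 1.000000
monthly  pooled r = 1.000000
seasonal pooled r = 1.000000
annual   pooled r = 1.000000
```

The fitted constants equal the generating reference row for station s1 to
machine precision (root-SSE ≈ 6e-16 ‰): with a covariate design spanning
the kink at x = b, the five constants are identifiable and the multi-start
search finds the global minimum. The −19.56 ‰ at the kink is the
mid-season (monsoon) depletion the function encodes. The second block
simulates a 13-station elevation-gradient network with noise switched off,
refits every site on its first growing season, transfers b to the two
later seasons, and predicts every sampling interval: pooled correlation is
exactly 1 at all four aggregation scales — the pipeline is self-consistent
end to end.

A command-line surface wraps the same stages:

```sh
evisoscape simulate --seed 3 --sites 13 --years 3 --out demo/
evisoscape smooth --in demo/evi.csv --out demo/smoothed.csv
evisoscape ievi --in demo/smoothed.csv --out demo/ievi.csv
evisoscape fit --obs demo/obs.csv --restarts 30 --seed 1 --out demo/constants.csv
evisoscape validate --seed 3 --sites 13 --years 3 --out demo/report.csv
```

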