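# forageq

Movement-ecology analysis linking GPS-tracked central-place foragers to a
prey habitat-suitability surface.  The package is built for the question a
colonial seabird study asks: *as energetic demands rise over a breeding
season, do birds occupy better foraging patches faster than the landscape
itself improves?*  It provides, as reusable and tested components, the full
chain from raw fix tables to that inference:

1. **Trip processing** — isolate complete same-day colony-to-colony
   foraging trips and rediscretize each track to constant 200 m along-path
   steps (`forageq.trajectory`).
2. **Foraging detection** — first-passage time (FPT): the time to traverse
   a circle of radius *r* centered on each path point.  The radius
   maximizing the across-bird mean variance of log FPT (scanned over
   100–5000 m at 100 m steps) is the characteristic scale of
   area-restricted search (ARS); points in the 90th percentile of FPT at
   that scale are the putative foraging locations (`forageq.fpt`).
3. **Prey distribution model** — a minimal presence-background maximum
   entropy (maxent) model over linear, quadratic, product and hinge
   features with per-feature L1 penalties scaled by a global
   regularization multiplier (default 2), 10-fold cross-validation, AUC,
   percent contribution and permutation importance, and complementary
   log-log ("cloglog") suitability output
   `s(x) = 1 − exp(−e^H · p_raw(x))` (`forageq.sdm`).
4. **Annotation and null model** — inverse-distance-weighted space-time
   annotation of points against gridded environmental layers (sea surface
   temperature, chlorophyll-a, salinity, bathymetry), and a resampling
   null that rebuilds 10,000 pseudo-foraging locations from the observed
   marginals of timestamp, colony bearing and colony distance
   (`forageq.annotate`).
5. **Seasonal inference** — trip-mean suitability `S ∈ (0,1)` modelled by
   a beta-likelihood additive model with logit link,

   `logit E[S] = β₀ + β_g·1[observed] + year effects + f_obs(day)·1[obs] + f_sim(day)·1[sim] + b_bird`,

   with penalized cubic-regression-spline smooths `f`, bird random
   intercepts as a ridge block, and smoothing parameters and precision φ
   chosen by Laplace-approximate REML.  A prediction-matrix difference
   smooth `D(d) = x_diff(d)·β̂ ± 1.96·SE` locates the days on which
   observed birds occupy significantly better or worse habitat than the
   null (`forageq.inference`).

A seeded synthetic-data module (`forageq.synthetic`) generates the whole
study — dynamic environmental rasters with known suitability ground truth,
thinned prey presence records, two-mode (transit/ARS) central-place
forager tracks, and bird morphometrics — so every stage is testable
without any external download.

## Worked example

Fit the seasonal model on simulated trip-quality data with a known
observed-vs-null offset of 0.5 logits and a 2016 year effect of 0.3:

```python
from forageq.inference import BetaGAM, simulate_trip_quality

tq = simulate_trip_quality(400, seed=1, group_effect=0.5,
                           year_effects={2015: 0.0, 2016: 0.3})
res = BetaGAM(tq).fit()
print(res.summary())
```

```
Beta-likelihood additive model (logit link)
  n = 800 trips, phi = 59.29, deviance explained = 58.2%

Parametric terms:
                 estimate        se          t             p
intercept        0.002317  0.015848   0.146187  8.837741e-01
group[observed]  0.525905  0.031736  16.571484  1.120269e-61
year[2016]       0.289717  0.018866  15.356887  3.185077e-53
```

The fit recovers the generating quantities: the group coefficient 0.526
(truth 0.5), the year contrast 0.290 (truth 0.3) and the beta precision
59.3 (truth 60).  `res.difference_smooth()` returns the day-by-day
difference with its 95% band and significance mask, and
`res.wald_year_contrasts()` gives pairwise chi-square tests between years.

The full pipeline runs from one command:

```sh
forageq all --seed 1 --outdir runs/demo
```

which writes per-stage outputs (trips, FPT profiles and the selected
scale, the fitted prey model with fold AUCs and variable importances,
annotated and null points, the difference-smooth table and figures) plus a
machine-readable `summary.json`.  On the packaged demo scenario the run
takes well under a minute and reports, e.g., a selected ARS scale of
2000 m for tracks generated with a 1500 m ARS patch radius, a mean
cross-validated AUC of 0.73, and a difference smooth that is significantly
negative early in the season and significantly positive late — the
designed ground-truth pattern of naive, range-restricted birds early and
strongly quality-directed foraging late.

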