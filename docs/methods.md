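# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limitations of the package.  Everything stated here
is computed by the test suite or the pipeline itself.

## Coordinate and raster conventions

All computation is in planar projected meters.  Longitude/latitude input
is projected on ingest with a local equirectangular projection about a
study-area origin; at the tens-of-kilometers scale of a central-place
forager study its distortion is second order and far below the 200 m
rediscretization step.  Gridded environmental layers are cell-center
registered square grids held as one layer per (year, Julian day), written
to disk as single-band TIFFs with a JSON georeferencing sidecar.

## Trip processing

Fixes are de-duplicated on exact (bird, timestamp) keys.  A *complete*
foraging trip is a maximal run of consecutive fixes outside a configurable
colony buffer (default 500 m — the island scale; no buffer is prescribed
by the study design) bracketed by colony fixes on the same local calendar
date; colony fixes themselves are excluded from the path.  "Same day" is
the calendar date, not a solar ephemeris.

Rediscretization places points at arc-length positions 0, s, 2s, …
(default s = 200 m) along the piecewise-linear path, interpolating
position and time within segments.  Two consequences worth stating
explicitly: the *along-path* spacing is exactly s, while straight-line
distances between consecutive points are shorter wherever the path turns
between samples; and the original final endpoint is appended so trips end
at the colony approach.  Paths shorter than one step are flagged
degenerate and excluded with a log entry.

## First-passage time

FPT at a path point is the time between the first crossings of the circle
of radius r centered on that point, scanning backward and forward along
the path.  On a piecewise-linear path the distance to a fixed center is
convex within each segment, so the first vertex beyond r identifies the
crossing segment exactly; the crossing position solves a scalar quadratic
and time is interpolated linearly within the segment.  A point whose
circle is never exited on one side (trip ends) has undefined FPT and is
excluded from statistics.  Tests verify the analytic straight-line law
FPT = 2r/v and agreement within 2 s with a brute-force oracle that walks
the path at 1 s resolution.

The characteristic ARS scale is the radius maximizing the across-bird
mean of the per-bird variance of log FPT over the 100–5000 m grid (50
radii, 100 m interval).  The aggregation sentence this rule implements is
ambiguous in the originating description; the package defaults to the
peak of the across-bird mean profile and exposes the alternative reading
(largest of the per-bird peak radii) as `scale_rule="per_bird_max"`.
Ties go to the smallest radius.  Foraging points are those at or above
the 90th percentile (linear-interpolation quantile) of FPT at the
selected scale; the reference distribution is per bird by default —
a per-trip reference would force retention inside pure-transit trips —
with per-trip and pooled options in config, and a pooled fallback when a
reference set has fewer than 10 defined values.

## Maximum-entropy prey model

The model is the standard presence-background maxent: over a background
sample B, minimize

    J(β) = log Σ_{i∈B} exp(β·f_i) − β·f̄_presence + Σ_j pen_j |β_j|,

pen_j = λ·sd_j/√n_presence with λ the global regularization multiplier
(default 2) and sd_j the background standard deviation of feature j.
Features are the min-max-scaled variables, their squares, pairwise
products, and forward/reverse hinges with 4 knots per variable at
background quantiles.  The objective is convex; it is minimized by cyclic
coordinate descent with an exact per-update objective change (used both
for step control and for the percent-contribution decomposition, with
product features crediting their two parent variables equally).  The
iteration cap defaults to 1,000,000 coordinate updates as a hard stop;
convergence is declared when a full sweep improves the objective by less
than 1e-8.  The fitted raw distribution is normalized over the background
(checked to 1e-9), and suitability is the cloglog transform
1 − exp(−e^H·p_raw) with H the entropy of the fitted distribution, so a
uniform model yields 1 − e⁻¹ everywhere.  Cross-validation partitions
presences into seeded folds, scores held-out presences against the full
background by the Mann–Whitney AUC (ties 0.5), and averages the per-fold
cloglog projections for the final surface.  Permutation importance
shuffles one variable across the presence+background evaluation points
and reports the normalized AUC drop.

## Annotation and the resampling null

Point annotation is inverse-distance-weighted (k = 4 neighbours, power 2;
both configurable, with k = None meaning all cells) over valid cells,
exact cell-center hits taking the cell value, and linear interpolation in
time between the bracketing layer dates.  The null model resamples — with
replacement and independently of one another — a timestamp, a colony
bearing and a colony distance from the observed foraging points
(n = 10,000 by default), placing each point at colony + d·(cos θ, sin θ);
independent resampling is the intended "random chance" landscape null and
breaks any joint bearing-distance structure, while `joint=True` resamples
whole rows instead.  Points falling on land (bathymetry ≥ 0) are redrawn
up to 100 times and kept (with a log entry) if still on land.  Simulated
points are grouped into pseudo-trips by simulated date so both groups
enter the seasonal model as trip means.  Trip means of exactly 0 or 1
(impossible from cloglog output, possible for externally supplied scores)
are compressed by (S·(n−1)+0.5)/n.

## Seasonal beta-likelihood additive model

Trip-mean quality S ∈ (0,1) follows a beta likelihood with common
precision φ and logit-linked mean

    η = β₀ + β_g·1[observed] + Σ_y β_y·1[year=y]
        + f_obs(day)·1[observed] + f_sim(day)·1[simulated] + b_bird.

The smooths use the cardinal cubic regression spline basis (coefficients
are function values at 10 knots placed at day quantiles) with the exact
integrated-squared-second-derivative penalty, sum-to-zero constrained
over the data rows by QR reparameterization.  Bird random intercepts form
an i.i.d. Gaussian (ridge-penalized) block with one level per real bird;
pseudo-trips of the resampling null have no individual and carry no
random-effect column.  Coefficients are fitted by penalized Fisher
scoring with step halving; the three smoothing parameters and φ are
selected by Nelder-Mead minimization of the negative Laplace-approximate
restricted marginal likelihood (an explicit unit-step initial simplex is
supplied — the scipy default barely perturbs zero starting coordinates
and stalls the search).  The final coefficient solve runs to a gradient
tolerance of 1e-9.  The reported covariance is the Bayesian posterior
covariance (inverse penalized Hessian); effective degrees of freedom are
the block sums of diag(V·XᵀWX); deviance explained compares the fit with
an intercept-only beta fit at the same φ.  The "share of explained
deviance attributable to fixed effects" is an interpretation choice:
the deviance-explained ratio of a refit with the bird block penalized out
to the full fit.

The difference smooth builds linear-predictor rows for each grid day
under the two group labels at the reference year with no bird effect,
differences them (intercept and year terms cancel; the group indicator
and the two smooths remain), and reports D(d) = x_diff·β̂ with the
normal-approximation pointwise band D ± 1.96·SE.  Evaluation outside the
fitted day range is refused unless explicitly allowed.  Pairwise year
comparisons are Wald chi-square contrasts with one degree of freedom.
Smooth-term p-values come from a block Wald chi-square with the rounded
effective degrees of freedom — an approximation, flagged as such.

Interval calibration, measured by the test suite under a flat shared
seasonal curve with no group difference (400 trips per group, 200 seeded
replicates): the pointwise interval covers zero at about the nominal rate
per day (mean day-wise coverage ≈ 0.94–0.96), while the fraction of
replicates covering zero on ≥ 90% of grid days is ≈ 0.88.  The latter
statistic would equal the nominal 95% only if day-wise coverage events
were fully dependent; residual independent wiggle in the two smooths
makes partial-coverage replicates possible, so the whole-curve summary
sits below the idealized value even though the interval itself is
nominal.  An mgcv cross-check on identical data covers on every day in
every replicate — conservative in the other direction, because its single
shared random-effect level for the simulated group inflates the group
standard error.

The trait model (sex, condition, year on logit trip quality with bird
random intercepts) delegates to statsmodels MixedLM under REML; singular
fits (zero between-bird variance) still deliver valid fixed effects and
are reported as such.  The body condition index is the per-sex
standardized residual of log mass on 3·log tarsus; a perfect allometric
fit leaves the index at 0 with a degeneracy flag.

## Synthetic study design

The generator encodes a known ground truth so each stage's output can be
checked against it.

*Environment* (60 × 60 km at 1 km cells, two seasons of Julian days
120–180 at 2-day steps by default): bathymetry is a static coastal ramp
(land to the north, deepening southward); salinity a fixed coastal
gradient; sea surface temperature warms linearly from 30.2 to 33.8 °C at
the offshore edge over the season with the coastal strip 1.5 °C cooler —
the thermal front crosses the 30–32 °C suitability ramp offshore first
and reaches the colony's coastal strip only late; chlorophyll-a is a
log-Gaussian patch field (six 6-km patches plus smoothed noise) whose
centroids drift at 250 m/day and whose level rises at 0.012/day, with
patch centroids confined offshore of the coastal strip.

*True suitability* is a product of responses: a logistic ramp centered at
31 °C with width (hi−lo)/8 so the rise is concentrated in 30–32 °C; a
smoothstep in chlorophyll exactly flat at and above 10 mg/m³; weak
unimodal Gaussian responses in salinity and depth; and a soft water gate
suppressing land.  Prey presences are thinned samples: uniform proposals
over the extent and dates accepted with probability equal to suitability,
so presence density is proportional to suitability (verified by a
two-stratum ratio test).

*Tracks*: each bird makes up to one round trip per layer date — fast
near-straight transit out, a slow high-turning bout confined within the
ARS patch radius (default 1500 m) at the destination, straight transit
back — with fixes every 900 s inside a 06:00–20:00 daylight window,
beginning and ending at the colony on the same date.  Destination choice
over reachable water is weighted by suitability^preference(t) times a
central-place taper exp(−d/L(t)), with L(t) relaxing from 5 to 60 km over
the season and the demo preference exponent rising as 6t².  Early birds
are therefore range-restricted to the cool, patch-poor coastal strip
(occupied quality below the landscape null); late birds range freely and
select strongly for quality (occupied quality above the null) — the
designed ground truth behind the demo's difference smooth, which the
end-to-end test asserts as a negative-early/positive-late significance
mask with a single sign change.

*Metadata*: tarsus is lognormal about a sex-specific mean and mass
follows a cubic allometry with lognormal noise clipped to the 2600–4330 g
range; a zero-noise option makes mass exactly proportional to tarsus³ as
a degenerate control for the condition index.

What the generator does not emulate: tides, currents, fish-school
dynamics, GPS error, solar daylight geometry, multi-colony systems, or
device failure patterns.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the methods under a controlled
data process, not field realism.

## Problem sizes

The packaged demo uses 6 birds × 2 seasons (about 300 trips and 7,000 ARS
points), 600 prey presences, 4,000 background points, 10-fold
cross-validation, and the full 10,000-point null; it completes in well
under a minute on one core.  Analysis defaults in `RunConfig` mirror the
study-scale settings (10,000 background points, 10,000 null points,
regularization multiplier 2, 1,000,000-iteration cap); the calibration
and recovery simulations in the test suite state their replicate counts
in the individual tests.

## Known limitations

- The maxent percent-contribution decomposition is path-dependent
  (coordinate-update order), as in the original algorithm; for strongly
  collinear variables the split between them is not identifiable.
- The beta GAM assumes a common precision φ across groups and years.
- Smooth p-values and the fixed/random deviance partition are approximate
  summaries, documented above.
- IDW annotation ignores layer uncertainty and land/sea masking beyond
  missing-cell exclusion.
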