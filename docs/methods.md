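# Methods

## The empirical CWSI model

The package implements the empirical (baseline) formulation of the crop
water stress index. Its assumptions:

* At a given atmospheric demand (VPD), the canopy–air temperature
  difference Tc − Ta of a well-watered, fully transpiring canopy falls on a
  linear **lower baseline** Tc − Ta = a·VPD + b with a < 0 (stronger
  evaporative cooling at higher demand). The baseline is crop- and
  season-specific, so it is calibrated per cultivar-year.
* A non-transpiring (fully stressed) canopy sits at a VPD-independent
  **upper limit** (Tc − Ta)ul > 0.
* A measurement's stress level is its linear position between the two
  references: CWSI = [(Tc−Ta)m − (Tc−Ta)ll] / [(Tc−Ta)ul − (Tc−Ta)ll].

No aerodynamic or net-radiation terms are modeled; the empirical approach
trades physical generality for calibration simplicity, which is why the
baselines must come from the same site, cultivar and season they score.

### Psychrometrics

VPD is computed from the simultaneously recorded air temperature and
relative humidity as es(Ta)·(1 − RH/100), with the FAO-56 Tetens
saturation curve es(T) = 0.6108·exp(17.27·T/(T + 237.3)) kPa. The source
study names only a "standard psychrometer equation"; the Tetens form is
this package's documented substitution (the study recorded RH directly, so
no wet-bulb depression formula is needed). The formula tag travels in
`VpdValue.formula` so an alternate curve can be swapped without ambiguity.
Air temperature is accepted in [−10, 55] °C and RH in [0, 100] %
(boundaries inclusive); outside is a hard rejection, not a clamp.

### Baseline calibration

* **Lower baseline**: OLS of Tc − Ta on VPD over well-watered observations
  taken exactly 3 days after irrigation, inside the 13:00–15:00 local
  midday window. The window is stated in the protocol only for the upper
  baseline; we apply it to all calibration-grade observations for
  consistency. The estimator is `scipy.stats.linregress` behind a single
  shared core (`regression.fit_line`) also used by the CWSI–trait
  relations; the test suite checks it against an independent
  normal-equation oracle at 1e−9. A fitted slope ≥ 0 is physically
  anomalous and warns rather than errors, so partial-season calibrations
  still run. Fewer than 3 points or zero VPD spread is an error.
* **Upper limit**: mean of the top decile of Tc − Ta over unirrigated
  observations in the midday window (≥ 5 required). The raw maximum is
  outlier-sensitive; a quantile-mean plateau is robust and configurable
  (`upper_quantile`). Under symmetric measurement noise around a true
  plateau this estimator is biased high by ≈ 1.75 σ (the mean of the top
  decile of a normal distribution); with the default 0.3 °C canopy noise
  that is ≈ +0.55 °C, which shrinks downstream CWSI by ~4–5 %. This is an
  accepted property of the robust estimator, visible in the end-to-end
  closure numbers, not a defect.
* Duplicate (plot, timestamp) records are an input error everywhere —
  silent double counting would bias every mean.

### Index computation and aggregation

CWSI is clamped to [0, 1] with an audit flag and the raw value retained:
field noise legitimately produces slightly negative values near the
baseline. The denominator must be positive; (Tc−Ta)ul ≤ (Tc−Ta)ll at the
observation's VPD is a hard error. Monthly means weight every record in a
group-month equally (the study does not state replicate weighting; this is
the documented choice), the seasonal mean is the **unweighted mean of the
monthly means** restricted to April–July (configurable) — verified to
reproduce all 16 published seasonal cells from their monthly cells — and
report rounding is **half-up** at the table's printed precision
(2 decimals for CWSI, 1 for color quality), implemented in decimal
arithmetic after quantizing the float at 1e−6 to absorb binary
representation error.

### Companion metrics

* Soil refill depth D = Σ(θfc − θᵢ)·ΔZᵢ in mm (θ dimensionless, ΔZ in mm);
  θ > θfc is rejected as supersaturated. Deficit regimes deliver a fixed
  fraction (1.00/0.75/0.50/0.25) of the refill depth per event — the
  proportional-per-event reading of "irrigation based on % FC", consistent
  with the near-proportional reported water totals.
* RWC = 100·(FW − DW)/(TW − DW), weights validated DW ≤ FW ≤ TW; the
  leaf-disc protocol constants (8 discs, 6 h soak, 70 °C/24 h) are carried
  as metadata only.
* The Munsell chart maps (page, value/chroma) to scores 9 (dark green,
  5GY 3/4) down to 2 (light green, 2.5GY 8/*), with the 2.5Y and 5Y pages
  collapsing to 1 (yellow, dead) for any value/chroma. The seasonal color
  mean includes the pre-stress initial (late-March) score alongside
  April–July — the only reading that reproduces all 20 published seasonal
  color cells.
* WUE is the definitional ratio seed yield / total water consumed. The
  published WUE cells are internally inconsistent with the published
  yield/water quotients (plausibly computed per replicate before
  averaging); the package computes the definitional ratio and does not
  chase the printed cells.

### CWSI–trait relations and regime classification

Relations are fit on per-plot-year aggregates (seasonal CWSI vs trait),
the granularity trait measurements actually have — 64 rows in the default
two-year scenario. Significance p-values come from the correlation
t-statistic and are presentation metadata. Predictions outside physical
range (e.g. negative yield at CWSI → 1) are returned with a warning.
Classification against the recommended band (default 0.28–0.33, endpoints
inclusive, overridable) is three-way: below = over-irrigated, inside =
acceptable deficit, above = under-irrigated; verdicts are computed both
per cultivar-regime and per regime (cultivars and years pooled).

## The synthetic experiment

The generator inverts the CWSI definition instead of simulating canopy
energy balance — its job is to give every pipeline stage data with the
right statistical structure, not to model physics.

* **Layout**: 2 cultivars × (4 regimes + unirrigated) × 4 replicates ×
  2 years, measurements every 3 days April 1 – July 31, regular plots read
  once at 13:30, unirrigated plots half-hourly 13:00–15:00.
* **Weather**: midday Ta interpolates the site's published monthly maximum
  temperatures per year (April ≈ 29.8 → July ≈ 42.7 °C in the first year);
  RH anchors 45/35/25/18 % April–July (not published; a realistic semi-arid
  decline, fixed once). Gaussian daily noise (σ 1.5 °C, 5 pp); zero noise
  reproduces the envelope exactly.
* **Stress trajectories**: each regime's true CWSI rises linearly from
  0.6× to 1.4× its seasonal target across the season, clipped to [0, 1].
  Per-regime targets are the means of the four published cultivar-year
  seasonal values: 0.205 (well-watered), 0.3025 (mild), 0.6125 (severe),
  0.70 (most severe); unirrigated is pinned at 1.
* **Calibration-day convention**: a freshly irrigated well-watered canopy
  transpires at potential, so well-watered events on the day-3 calibration
  cycle are generated exactly on the lower baseline (true CWSI 0), and the
  regime's stress is carried by the between-irrigation events, rescaled by
  interval/(interval−1) so the cycle mean stays on the trajectory. Without
  this the calibration set would not estimate the baseline it is defined
  by. The measurement interval must therefore be ≥ 3 days.
* **Thermometry noise**: event-mean canopy noise σ = 0.3 °C plus
  independent 0.2 °C directional jitter on each N/S/E/W reading (effective
  σ ≈ 0.32 °C on the four-direction mean).
* **Traits**: seed yield = −1695.4·CWSI + 1601.3 (σ = 50 g m⁻²) and
  RWC = −79.129·CWSI + 81.316 (σ = 2 pp) from the published relations;
  color score is a deterministic monotone step function of seasonal CWSI;
  water totals are fc_fraction × the cultivar-year well-watered irrigation
  base (570.3 mm Goldasht first year, up to 633 mm Local Isfahan second
  year, anchored to the published range) plus the fixed rainfall schedule.
  A leaf-weight table is emitted whose RWC inverts exactly.
* **Determinism**: one `numpy` Generator seeded from the config; identical
  config + seed gives byte-identical CSV output.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: energy-balance physics (no radiation, wind or
stomatal dynamics), spatial replicate structure (replicates differ only by
noise, so split-plot error strata are absent), weather autocorrelation and
rainfall stochastics, sensor drift, and missing-data patterns. Closure
tests demonstrate the *statistics* recover the generating parameters, not
that the model captures field physiology.

## Problem sizes and tolerances

The default scenario produces 5 904 observations (52 lower-baseline points
and 820 upper-limit points per cultivar-year); the full run takes ~1 s.
Parameter-recovery checks use 50 seeded calibrations of 200 points at
σ = 0.3 °C, asserting mean absolute slope error < 0.05 °C kPa⁻¹ and
intercept error < 0.1 °C (the analytic standard errors are ≈ 0.015 and
≈ 0.06, so the bounds are comfortable but not vacuous). End-to-end, the
calibrated upper limit is accepted within 1 °C of truth (the documented
plateau-estimator bias ≈ +0.55 °C at default noise). Exact algebraic
checks (CWSI endpoints and midpoint, collinear refits) are asserted at
1e−9–1e−12.

## Known limitations

* The empirical baselines are site/season-specific; applying a calibrated
  `BaselineModel` to another site is scientifically invalid and the
  package does not guard against it beyond the cultivar-year join.
* The upper-limit estimator's bias means absolute CWSI levels are ~4–5 %
  conservative at default noise; regime *comparisons* are unaffected.
* The Local Isfahan lower-baseline intercept is not published; the
  synthetic default (0.6 °C) is an anchoring choice and recovery of that
  cultivar's intercept is only meaningful relative to the configured value.
* Split-plot ANOVA / LSD mean separation of the original analysis is out
  of scope; use statsmodels on the exported per-plot tables if needed.
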