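# Methods

## Speed-over-ground model

A positioning array yields irregular fixes (tag, UTC time, lat, lon,
HPE, optional depth). Horizontal swim speed for each consecutive pair
of one animal is the WGS84 inverse-geodesic (Vincenty) distance over
the elapsed time. Because fixes are position estimates, not positions,
three filters precede any inference, applied in this fixed order:

1. **HPE ≤ 5 m** (inclusive). HPE is the positioning algorithm's
   per-fix horizontal error scale; 5 m keeps error well below typical
   inter-fix displacements.
2. **Elapsed time ≤ 300 s** (pairs above are removed). Long gaps make
   distance-over-time a poor proxy for instantaneous speed because the
   path between fixes is unknown.
3. **SS_H ≥ 0.1 m/s** (exclusive floor). Sub-floor estimates are
   dominated by position jitter while the animal mills about.

The gap filter is booked before the speed floor, so a slow pair over a
long gap counts against the gap filter. Zero-elapsed pairs (duplicate
timestamps that survive ingest) are dropped and counted separately.

True swim speed assumes a constant dive angle between fixes:
SS_T = √(dist_h² + Δdepth²)/Δt, computed for the pairs that survive
the SS_H filters (the floor is applied to SS_H only, then SS_T is
derived for the survivors). SS_T ≥ SS_H always; equality iff
Δdepth = 0.

Medians are the headline statistic throughout — speed distributions
are strongly right-skewed — with SE = sd/√n alongside; the median of
an even-length sample is the mean of the central pair, and singleton
groups report SE = 0 flagged by n = 1. Pearson correlations against
covariates are reported without p-values: serial autocorrelation makes
the nominal significance machinery misleading, so they are
descriptive.

Day/night is classified at the array centroid by geometric sun
elevation (NOAA solar-position equations, accurate to ~0.01°); day is
elevation ≥ 0, so the sunrise/sunset instants are day. Latitudes
beyond ±66° are rejected rather than mis-handled (polar day/night is
out of scope). Covariates (depth, temperature) join at the pair
midpoint time and the mean of the endpoint depths; the midpoint
position is the coordinate mean, adequate at tens-of-metres pair
separations.

Transit speed between two arrays divides the geodesic distance from an
animal's last fix at the origin by the time to its first detection at
the destination. Since the actual path is unknown these are lower
bounds; animals whose transit time exceeds the cohort median
(strictly) are excluded from the summary to limit dilution by animals
that lingered en route.

Geodesics use a vectorised Vincenty inverse on WGS84 written for this
package (verified against an independent geodesic implementation to
sub-millimetre agreement); near-antipodal non-convergence — impossible
at telemetry scales — falls back to a logged great-circle distance.

## Metabolic-rate estimators

**Speed regression (mass-specific fRMR).** MO₂ = SMR · 10^(slope·U)
with U in total lengths per second. Defaults: SMR = 246
mg O₂ kg⁻¹ h⁻¹ (empirical standard metabolic rate of captive
young-of-the-year white sharks; the U = 0 intercept) and slope 0.58
(mako swimming-performance curve). All logarithms are base 10. No
temperature correction is applied: the temperatures the tracked sharks
occupied overlap the range at which the SMR intercept was measured.
The regression is strictly increasing and log-linear in U;
`speed_from_frmr` inverts it exactly. Slope sensitivity is exposed
over {0.58, 0.79, 0.97} — the estimate at U = 0.3 spans roughly
367–481 mg O₂ kg⁻¹ h⁻¹ across published slope choices, which is the
dominant uncertainty in the method.

**Allometric whole-body RMR.** RMR = a·M^0.79 in mg O₂ h⁻¹. The
coefficient `a` (antilog of the lamnid-curve intercept) is not
published as a number and therefore has **no default**: callers must
supply it or back-solve it from a published whole-body rate at a known
mass. Supplying it implicitly would hide a load-bearing literature
choice.

**Length conversions.** FL = 0.9·TL (factor recovered from the
bundled cohort's printed length pairs; configurable) and
M = a·FL^b with (a, b) fitted by least squares in log10 space to the
cohort's (FL, mass) pairs (≈3.57·10⁻⁶, 3.25 — the usual near-cubic
length–weight law). These are calibrated to the bundled table rather
than hard-coded from external literature, and the fit function is
public so users can recalibrate to their own morphometrics.

## Block bootstrap

Two-sample median comparisons use a moving-block bootstrap: blocks of
length L (default 100) starting at any admissible index are drawn with
replacement, concatenated, and truncated to the original series
length; each of the two series is resampled independently (groups are
different animals/periods, not paired). The test statistic is
median(a) − median(b); the two-sided p-value is
2·min(P(Δ* ≤ 0), P(Δ* ≥ 0)) with a +1/(B+1) continuity correction, so
p is never exactly 0 and the resolution floor is 2/(B+1). A percentile
(1−α) interval of the bootstrap differences is returned alongside.
Pairwise tests across k groups run all k(k−1)/2 comparisons at the
Bonferroni level α/n_pairs (three sex classes: 0.05/3 ≈ 0.0167).

Design choices where the procedure was under-determined: moving rather
than non-overlapping blocks (switchable via `overlap=False`);
truncation as the closure of the final partial block; and block
stratification within animal — a group composed of several sharks is
passed as a list of per-animal series and blocks never span two
animals. Simulation on AR(1) nulls (φ = 0.7, n = 2,000) shows the
blocked test holds its nominal 5% level while a block-length-1
(unblocked) bootstrap over-rejects severely — the motivating failure
of naive tests on autocorrelated data. Stationary/tapered bootstraps
and automatic block-length selection are out of scope.

## Temperature interpolation network

Water temperature is modelled as f(lat, lon, depth, day-of-year,
time-of-day-minutes) by a fully connected ReLU network: an input layer
to width w, hidden layers at width w, and a final linear map to a
scalar. The full-scale spec is 11 hidden layers × 128 (166,017
parameters on 5 inputs — the parameter-count identity
5·128+128 + 10·(128²+128) + 128+1 is asserted in tests); the desk
spec used by tests and examples is 3 × 32 for 10 epochs, which
reaches holdout MAE ≈ 0.18 °C on a noiseless stratified field —
under the 0.3 °C accuracy target at a few hundredths of the cost.
Training uses Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 10⁻⁸), batch 128,
squared-error loss (MAE is the reported metric, not the training
loss), via scikit-learn's MLPRegressor behind this module's surface.
Inputs are z-scored and the target standardised — a conditioning
choice, with parameters stored on the model and inverted at
prediction — and a seeded 90/10 random holdout supplies both training
and holdout MAE, since training error alone overstates accuracy.
Time features are raw by default with an optional sine/cosine cyclic
encoding (`cyclic_time=True`); raw values match the stated input list
and suffice for a single-season field. Fitting is bit-reproducible
under a fixed seed on one thread.

## UAV photogrammetry

gsd = sensor_dim_mm · altitude_m / (focal_mm · image_dim_px), by
default along the image height axis, which is the calibrated axis for
the bundled camera (8.8 mm over 2160 px gives 0.0278 m/px at 60 m).
Camera constants are manufacturer values, recorded as such. Per-step
speed is the Euclidean pixel displacement times gsd over the step
interval — the frame interval is always taken from the track's own
timestamps, never assumed; tracks present for less than 60 s
(exclusive) are rejected as too short to characterise cruising.
Body length is pixel span times gsd; zero-pixel measurements are
flagged invalid. Lens distortion is ignored (nadir camera, centred
subjects); video decoding and object tracking are out of scope —
pixel tracks are the input.

## Synthetic data

The generators define the conditions every statistical claim in the
test suite is evaluated under; they emulate the telemetry regime of a
nearshore nursery array, not open-ocean movement.

* **Tracks**: correlated random walk (von Mises heading increments,
  concentration 4) with per-segment speeds log-normal around a median
  of 0.6 m/s (log-sd 0.5, right-skewed, range reaching a few m/s); a
  multiplicative day/night factor √1.08 vs 1/√1.08 (≈0.64 vs
  0.59 m/s) switched on solar elevation at the array centroid; a 3%
  resting state uniform on (0, 0.12) m/s so the 0.1 m/s floor is
  exercised; exponential inter-fix gaps with mean 120 s so ≈8% of
  gaps exceed the 300 s filter. HPE is log-normal, solved numerically
  to have mean 3 m and P(HPE > 5) = 0.10 (infeasible combinations are
  rejected, since a fixed-mean log-normal bounds the exceedance
  probability); observed positions add Gaussian jitter of sd HPE/2
  per axis — HPE is an error scale whose exact mapping to a jitter sd
  is unpublished, so this choice is documented and controlled via the
  config. Walks are laid onto the ellipsoid with local WGS84 radii so
  step lengths survive the inverse geodesic to ~10⁻⁴ relative.
  Ground-truth positions and per-segment speeds are kept alongside
  the observables.
* **Temperature**: T = surface − strat·depth + A·sin(diel) + noise,
  defaults 20 °C surface, 0.2 °C/m to 40 m, 1 °C diel amplitude
  peaking at 15:00 — spanning ≈12–22 °C like a stratified nearshore
  column — with the noiseless field exposed for MAE evaluation.
* **UAV**: straight constant-speed pixel tracks (displacement
  speed·Δt/gsd per frame); **AR(1)** series for bootstrap
  calibration.

What the generators do *not* emulate — tides and currents, detection
probability physics, tag collisions, path tortuosity between arrays,
habitat preference — bounds what passing tests show: they demonstrate
the pipeline recovers known kinematic and statistical structure from
data with the assumed error model, not that the error model is the
ocean's. Jitter inflates distances on short gaps, so the recovered
median speed sits a few percent above the configured value at the
default HPE; the recovery test's 5% band is a property of that error
model, and the bias shrinks as HPE → 0.

## Numerical and scale choices

Test-suite problem sizes are chosen for a laptop-class run: ~5,000-fix
tracks for recovery, 1,000 AR(1) replicates at n = 2,000 with 500
resamples for the level check, 5,000 observations for the network.
Vincenty iterates to 10⁻¹² rad (~200 iterations cap); duplicate fixes
are dropped keep-first at ingest (the handling of duplicates is this
package's documented choice — ordering within a duplicate pair is not
meaningful in vendor exports); all timestamps are strict UTC
internally with the input timezone declared in the schema config.
Every stochastic component takes an explicit seed and is
bit-reproducible under it.

## Known limitations

Transit speeds are path-unaware lower bounds. The diel boundary
(geometric horizon) ignores twilight. The fRMR regression inherits the
uncertainty of its slope and intercept — the slope choice alone moves
estimates by tens of percent, which is why the sensitivity table is a
first-class output. Whole-body RMR requires a user-supplied allometric
coefficient. The temperature network at full scale is only as good as
observation coverage; extrapolation beyond the sampled envelope is
unguarded.
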