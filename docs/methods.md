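# Methods

`kelptrack` analyses passive acoustic telemetry from a coastal receiver
array: moored receivers log time-stamped decodings of coded transmitters
implanted in fish. From those detection logs the package derives
residency, short-interval positions, home ranges and their overlap with
marine protected areas (MPAs), a distance–detection model, and a
two-part model of hourly movement rates. This note records the models,
their assumptions, the defaults, and the numerical choices.

## Coordinates and time

All planar work uses a local equirectangular projection on a spherical
Earth (R = 6371 km): `x = R·cos(lat0)·Δlon`, `y = R·Δlat`. Over the
≤10 km extent of a kelp-forest array the distortion is below 0.5%,
far below the positional uncertainty of acoustic detections; a geodesic
ellipsoid would add dependency weight without measurable benefit.
Distances between geographic points (range testing) use the haversine
great-circle formula on the same sphere.

Timestamps are stored UTC. Every day-resolution quantity — the
tagging-day filter, days at liberty, detection-day counts, COA bin
alignment — is evaluated in a configured local zone (default
`America/Los_Angeles`), because field days are civil local days. COA
interval starts are reported as naive local wall-clock times; binning is
by wall-clock floor, so the two annual daylight-saving transition hours
are binned by their local labels.

## Detection filtering

Two rules, applied in order:

1. **Tagging day** — all detections on the local calendar date of the
   fish's release are dropped, excluding post-handling behaviour.
2. **Code collisions** — within each (tag, receiver) stream, scanning
   forward in time, any detection closer than `min_gap` seconds to the
   last *retained* detection is dropped. The default `min_gap` is 30 s,
   the minimum programmed delay of the emulated tag duty cycle
   (30–120 s). Retaining the earlier member of a too-close pair and
   comparing against the last retained (not last raw) detection makes
   the rule a deterministic single pass, and idempotent. Transmission
   duration is hardware-specific, so `min_gap` is configurable.

Both filters return subsets of their input and are idempotent; the
pipeline logs row counts dropped at each stage.

## Days at liberty and residency indices

`study_days = (study_end − release_date) + 1` counts local calendar days
inclusive of the release date. The inclusive convention is deliberate:
it is the one that exactly reproduces published per-fish summaries for
this kind of study (the day-after-release convention is off by one).
`array_days` spans first to last detection date inclusive, 0 with no
detections. The study residency index is `days_detected / study_days`;
the array index is `days_detected / array_days` (0 when undefined).
Since both indices share a numerator and `array_days ≤ study_days`,
array residency ≥ study residency always. Indices are reported to three
decimals.

## Centers of activity (COA)

Within half-open intervals aligned to local midnight (30 min for space
use, 10 min for movement rates), a fish's position estimate is the
detection-count-weighted mean of the coordinates of the receivers that
heard it. Single-detection intervals are kept — a one-detection COA at
the receiver position is a valid (if coarse) estimate under the weighted
-mean definition. Intervals with no detections emit nothing. The COA is
translation-equivariant with the station coordinates and always lies in
the convex hull of the contributing stations.

## Detection-range model

Range testing drifts a transmitting tag away from a moored receiver
while a mobile receiver records every transmission; pairing the two logs
gives per-ping binary outcomes at known distances. The model is a
logistic mixed regression with a per-receiver random **slope**:

    logit p_ij = β0 + (β1 + b_j)·d_ij,   b_j ~ N(0, σ_b²)

A shared intercept encodes that a tag at the mooring is heard equally
well anywhere; receivers differ in how fast detectability decays (kelp
vs. sand). The detection range is the 50% distance
`d50 = −β0/(β1 + b_j)` (global: `b_j = 0`). Downstream consumers use the
global d50, adopting the usual simplification of a constant array-wide
range; time-varying range (diel noise, currents) is out of scope.

### Estimation: Laplace marginal likelihood

No installed Python library offers a frequentist binomial GLMM
(statsmodels' `BinomialBayesMixedGLM` is a Bayesian variational
estimator), so `kelptrack.glmm` implements the Laplace-approximated
maximum-likelihood fit for the one-scalar-random-effect-per-group case,
which covers both uses in this package (random slope over receivers;
random intercept over individuals):

* for a candidate σ, the joint penalised log-likelihood in (β, b) is
  concave and maximised by Newton's method with step-halving;
* the Laplace correction factorises over groups because each group
  carries a single scalar effect:
  `ℓ(σ) = Σ log p(y|β̂,b̂) − Σ_g b̂_g²/2σ² − ½ Σ_g log(1 + σ²·Σ_{i∈g} w_i z_i²)`;
* the outer problem is a bounded one-dimensional search over log σ,
  warm-started between evaluations. As σ→0 the objective tends to the
  pooled logistic likelihood, so the pooled fit is the exact boundary
  case (and the fallback for single-group data).

Fixed effects are taken at the joint penalised mode (the profile-Laplace
shortcut); with hundreds to thousands of observations per group the
difference from re-optimising β inside the integral is far below one
standard error. Adaptive Gauss–Hermite quadrature is unnecessary at
random-effect dimension one with these group sizes; the accuracy
tradeoff is the standard Laplace one. Standard errors condition on σ̂
(the fixed-effect block of the inverse joint Hessian), matching common
mixed-model practice. Perfectly separable data (likelihood unbounded,
fitted probabilities saturated) raise a `SeparationError` advising a
pooled or penalised analysis rather than returning divergent estimates.
The tests cross-check the estimator against two independent routes:
pooled logistic regression (statsmodels `Logit`) in the σ=0 limit, and
R's `lme4::glmer` on the same random-slope model.

## Kernel utilization distributions

The utilization distribution is a fixed-bandwidth kernel density of the
projected 30-min COAs with an isotropic bivariate-normal kernel,
evaluated at cell centres of a regular grid (default 25 m cells) that
covers the points plus ≥3 bandwidths of padding, then renormalised to
unit mass. The bandwidth is the ad-hoc (reference) rule

    h = 0.5·(sd_x + sd_y)·n^(−1/6)

which assumes a bivariate-normal UD; the single scalar h is shared by
both axes (anisotropic smoothing is a non-goal). The kernel is
separable, so the density accumulates as one outer product per point
chunk (a matrix product), keeping 10⁴ points × 10⁴ cells well under a
second.

Volume contours (50% "core use area", 95% "home range") are the minimal
highest-density cell sets reaching the level: cells ranked by density,
ties broken row-major, cumulative mass cut at the level. Contour areas
are cell counts × cell area. Land clipping removes cells whose centres
fall inside land polygons and does **not** redistribute the removed mass,
mirroring post-hoc removal of the terrestrial sliver of a coastal home
range. MPA overlap is the fraction of contour cells whose centres fall
inside management polygons; the cell-centre point-in-polygon choice (over
exact polygon intersection) has error vanishing with cell size and keeps
the geometry dependency to plain shapely predicates. Seasonal splits
partition COAs by calendar month of the interval start; the spawning
season for this species is May–October.

Useful exact checks, used in the tests: for an isotropic normal UD the
95% contour area is π·χ²₂(0.95)·σ² and the 95%/50% area ratio is
ln 0.05 / ln 0.5 ≈ 4.32.

## Diel, lunar, and monthly covariates

Sunrise, sunset, and civil twilight come from the NOAA solar-position
formulas (low-precision Fourier expansions of declination and the
equation of time; ~1 min accuracy at mid-latitudes, against one-hour
windows). The diel classes are conventions, configurable and flagged as
such: dawn = [civil dawn, sunrise+1 h), day = [sunrise+1 h, sunset−1 h),
dusk = [sunset−1 h, civil dusk), night = the remainder. Latitudes above
60° are rejected rather than mishandled. Lunar phase uses the mean
synodic cycle (29.530588 d anchored at the 2000-01-06 18:14 UTC new
moon) quartered with *new* centred on 0° and *full* on 180°; true
ephemeris phase can drift ±0.6 d from the mean cycle, immaterial for
quarter-cycle categories. Month is the local calendar month, entering
the models as a 12-level factor. Reference levels are dawn, new moon,
and January; when a reference level is absent from a data subset the
first present level takes its place to keep the design full rank.

## Hourly movement rates and the hurdle model

From 10-min COAs, an hour contributes a record only when all six of its
bins produced a COA for the tag (movement cannot be measured while the
fish is outside detection range); the rate is the sum of the five
consecutive inter-COA distances, in metres per hour. Hours are
non-overlapping local clock hours; covariates are evaluated at the hour
midpoint. A rate of exactly 0.0 m — all six COAs identical, i.e. the
same single receiver — is common and meaningful, so no epsilon threshold
is applied.

The zero-inflated rates are modelled in two parts, each with a random
intercept per individual (the most complex structure such data support —
random slopes routinely fail to converge here):

* **binary part** — `logit P(rate>0) ~ diel + lunar + month + (1|fish)`,
  fit by the Laplace estimator above;
* **positive part** — `rate | rate>0 ~ same`, a linear mixed model fit
  by REML via statsmodels `MixedLM`. The Powell optimiser is used
  because gradient methods can stall on a singular profile solve when
  the variance component sits on its boundary; boundary fits warn and
  report σ_α = 0.

Inference is by Wald tests against a normal reference. Satterthwaite
degrees-of-freedom corrections were considered and rejected: they add
heavy machinery and at these sample sizes (thousands of hourly records,
t-statistics with thousands of denominator degrees of freedom) the
normal reference is indistinguishable.

Pseudo-R² values follow the variance-partition scheme with the
delta-method observation-level variance:

    marginal    = σ²_f / (σ²_f + σ²_α + σ²_d)
    conditional = (σ²_f + σ²_α) / (σ²_f + σ²_α + σ²_d)

where σ²_f is the variance of the fixed-effect linear predictor over the
data, σ²_d = σ_e² for the linear part, and σ²_d = 1/(p̄(1−p̄)) for the
logit part with p̄ the mean fitted probability. Conditional ≥ marginal
always.

## Synthetic data: what it emulates and what it does not

The simulator exists so every stage is testable without field data. It
reproduces the *statistical* structure the analyses assume:

* **Array** — 29 receivers on a jittered grid at 500 m spacing (the
  density of a ~29-receiver array over an ~8 km² kelp forest), depths
  11–25 m, a 70% kelp flag.
* **Movement** — a discretised Ornstein–Uhlenbeck walk:
  `Δ = −κ(pos−centre)·dt + s·√dt·ε`, κ = attraction/3600 s⁻¹. Defaults:
  attraction 0.3 h⁻¹ and step SD 1.2 m·s^(−1/2), a stationary
  home-range SD of ~93 m — strongly site-attached fish, which is what
  produces long runs of single-receiver detections and hence genuinely
  zero hourly rates. The step SD is multiplied by diel (day 2.0, night
  0.6) and monthly (May–Aug 1.3–1.6) factors, so diel/seasonal activity
  signals appear directly in realised movement rates. Scenario activity
  centres are anchored near receiver moorings, because receivers are
  deployed on the reef features fish hold on.
* **Transmissions** — renewal process with i.i.d. uniform 30–120 s gaps
  (expected ping rate 1/75 s⁻¹), positions interpolated on the track.
* **Detections** — each ping detected independently at each station with
  `p = logistic(β0 + (β1 + b_j)·d)`, b_j drawn once per station. The
  defaults β0 = 9, β1 = −0.0412 put the global 50% range at ~218 m with
  near-certain detection at the mooring and essentially none beyond
  400 m — the steep decay real kelp-forest range tests show — and
  σ_b = 0.005 spreads per-receiver 50% ranges over roughly 180–280 m.
* **Range tests** — constant-velocity drifts away from a mooring with
  per-ping detected/missed outcomes.

Not emulated: spawning-aggregation behaviour, acoustic propagation
physics, tidal/diel noise in detection probability, emigration dynamics
beyond a hard truncation time. Consequently, passing tests demonstrate
that the estimators recover known structure from data satisfying the
model assumptions — not that real fish satisfy them.

## Problem sizes and numerics

Calibration tests use 100 replicates at the design scale of the
emulated study (range model: 6 receivers × 2000 pings; hurdle parts:
5 individuals × 2000–5000 hourly records), asserting parameter recovery
within three reported standard errors in ≥90% of replicates. The
end-to-end scenario uses 4 fish × 10 days on the full 29-receiver array,
a size chosen by a pilot power analysis so the known day-elevated
activity signal is detected reliably; 50 replicates run in under a
minute. The outer GLMM search uses a bounded golden-section pass with
tolerance 1e-4 on log σ; inner Newton iterations stop at a relative step
below 1e-10 or gradient below 1e-8·n. Degenerate inputs fail loudly:
fewer than two points (bandwidth), zero variance in both axes, empty
contours after clipping, non-positive intervals, polar latitudes.

## Known limitations

* The movement-rate construction conditions on six consecutive COAs,
  which over-samples periods of high detectability; no bias correction
  is applied (matching standard practice).
* The Laplace fit's fixed effects come from the joint penalised mode;
  at very small group counts or sizes this is mildly biased toward zero
  variance relative to full Laplace ML.
* Wall-clock COA binning makes the two daylight-saving transition hours
  locally ambiguous; they are binned by label.
* The equirectangular projection and spherical distances are unsuitable
  for arrays spanning more than a few tens of kilometres.
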