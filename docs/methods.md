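# Methods

`whalemove` implements the behavioural analysis chain used for satellite-tracked
Southern Ocean humpback whale migrations: Argos track regularization by a
state-space model, two-state hidden Markov movement modelling with sex
covariates, multiple-imputation pooling of parameter estimates across track
realizations, and spatial residency summaries against Southern Ocean
management areas. Because the original telemetry is held in a non-public
database, the package ships a ground-truthed synthetic generator that
emulates the study system, and validates every stage against it (plus the
published per-whale summary table, which is packaged as a fixture).

## Geodesy

All great-circle mathematics (distances, forward azimuths, the direct
problem, the azimuthal-equidistant projection used by the state-space
filter) runs on a single sphere of radius 6371.0088 km. Using one sphere
everywhere keeps the simulator, the filter and the feature computation
mutually consistent; ellipsoidal corrections are two orders of magnitude
below the positional noise at the scale of 6-h whale movement steps.

## Synthetic track generator

The generator is first-class, tested code; its defaults are the study
conditions:

* **Latent states.** A 2-state Markov chain (transit / resident) on 6-h
  steps with switching probabilities Pr(resident|transit) = 0.035 and
  Pr(transit|resident) = 0.017 (the published pooled estimates), implying
  67.3% stationary residency.
* **Movement.** Per state and sex, step speed is gamma distributed
  (mean/SD parameterization) and the step-to-step turning angle is wrapped
  Cauchy. Speed means are the published per-sex estimates (transit:
  5.15 / 3.16 / 4.00 km h⁻¹ for females / males / unsexed; resident:
  2.15 / 0.89 / 0.85); speed SDs default to mu/2 (the source reports CIs for
  the means only, so the dispersion is a package choice). Transit turning is
  concentrated at zero (kappa 0.62 / 0.38 / 0.60); resident turning is
  near-uniform with mean pi (kappa 0.1), matching the qualitative published
  description ("close to pi", "close to zero concentration"). The first
  step's heading is a supplied initial bearing; each later heading adds a
  wrapped-Cauchy turn; positions advance along great circles. The state is
  attached to the step (interval), not the vertex, matching the step/turn
  indexing downstream.
* **Argos degradation.** Observation times are exponential with a 2-h mean
  gap (matching the raw-to-filtered location ratio of the study: ~12 raw
  fixes per day), optionally truncated by tag dropout. Each fix draws a
  location class from a configurable distribution (default weighted toward
  the poor A/B classes, as is typical of whale-deployed tags) and isotropic
  Gaussian positional error with per-class SDs 0.25 / 0.5 / 1.5 / 4 / 6 /
  10 km for classes 3 / 2 / 1 / 0 / A / B. The original analysis defers to
  its filter's published error model; these explicit SDs are a package
  choice in the range used by that literature. The true gap process of the
  tags is not documented; exponential gaps are a modelling choice.

The generator does **not** emulate behaviour-dependent tag duty cycling,
dive behaviour, land avoidance, or heavy-tailed Argos errors. Tests passing
on these synthetics therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to every feature of real
Argos data.

## Track regularization (state-space model)

The latent movement process is a first-difference correlated random walk on
a locally planar azimuthal-equidistant projection (km) about the track
centroid:

    x_t = x_{t-1} + gamma_c (x_{t-1} - x_{t-2}) + eta_t,   eta_t ~ N(0, sigma^2 I),

on a regular 6-h grid anchored to wall-clock multiples of the step (four
estimates per UTC day). An irregular fix at time tau in (t_{k-1}, t_k]
enters the observation equation through its linear interpolation weight
w = (tau - t_{k-1})/step, with independent normal errors whose SD is set by
the fix's Argos class. The model is linear-Gaussian, so filtering,
smoothing (RTS) and likelihood evaluation are exact; (gamma_c, sigma) are
estimated by maximum likelihood (Nelder-Mead on tanh/log-transformed
parameters; the filter is started from the first observation with diffuse
variance 1e4 km² on both initial states). Reporting gaps longer than 7 days
(configurable) split a track into independently fitted segments. Track
realizations for multiple imputation are exact joint draws from the
smoothing distribution via forward-filter backward-sampling.

Two deliberate simplifications relative to the original filter: observation
errors are normal rather than t-distributed per class, and there is no
speed/angle pre-filter on the raw fixes (the source describes none). Both
are adequate for validation against the generator, whose errors are
themselves Gaussian.

## Step/turn features and the Southern Ocean filter

Step speed is great-circle length divided by the actual time delta
(km h⁻¹ — the published estimates are reported in these units); the turning
angle is the wrapped difference of successive forward azimuths, undefined
(NaN) at each segment's first step and around zero-length steps. The
behavioural analysis uses only positions strictly south of 36°S ("beyond
36°S" is read as lat < -36, configurable); runs broken by the filter are
re-segmented so no step or turn straddles excluded territory.

## The movement HMM

Two states (transit = 0, resident = 1); per state a gamma speed density
(shape = mu²/sigma², scale = sigma²/mu) and a wrapped Cauchy turn density
f(t) = (1-kappa²) / (2π (1+kappa² - 2 kappa cos(t - lambda))). Four
configurations express the sex covariate: (1) none, (2) sex on transitions,
(3) sex on movement parameters, (4) both. When sex enters the movement
parameters, the full emission set (mu, sigma, lambda, kappa) is triplicated
across the three sex levels — "unknown" is a genuine third level, never
pooled — giving 10 / 14 / 26 / 30 free parameters for configs 1-4 (initial
state weights are fixed at the stationary distribution of the applicable
transition matrix and add none).

Fitting maximizes the pooled log-likelihood over animals (segments are
independent chains sharing parameters) by L-BFGS-B on working scales:
log mu, log sigma, logit kappa, logit switching probabilities. The mean
turn angle lambda is optimized unconstrained and wrapped to (-pi, pi] on
output: the likelihood is periodic in lambda, so this parameterization is
smooth everywhere — including at the resident state's near-pi mean, where a
tangent-type link would diverge. Initial values are moment-based (median
split of the speeds); restarts jitter them (default 10; the heavy validation
runs use 2, which the moment-based start makes sufficient in practice).
States are identified post fit by ordering mean transit speed above mean
resident speed. Exact zero speeds receive an estimated per-state point
mass; the two extra parameters appear only when the data contain zeros.
The scaled forward recursion floors the normalizer at 1e-300 and is
numba-compiled, as is Viterbi decoding (ties resolved toward transit);
posterior state probabilities come from a scaled forward-backward pass.

Model selection uses AIC (the field default; the source states only "best
supported"); BIC is available as an option, and exact AIC ties resolve
toward fewer parameters.

## Multiple-imputation pooling

Rubin's rules on the working scale: pooled estimate = mean of the m
per-realization estimates; total variance = W + (1 + 1/m) B with W the mean
within-fit variance (inverse-Hessian diagonal) and B the between-fit sample
variance; 95% CIs use the normal quantile (a t quantile with Rubin's
degrees of freedom is available for small m) and are back-transformed
through the monotone links. Angular (lambda) estimates are first wrapped
onto the branch centred on their circular mean so fits straddling +/-pi do
not inflate B; their point estimate and CI are reported on that continuous
branch. Percentile pooling across the m natural-scale estimates is offered
as an alternative. The default m is 100, mirroring the study protocol;
validation runs use m = 10.

A property worth stating plainly: pooled estimates *reflect location
uncertainty by construction*. Because every imputed realization carries
residual positional noise, apparent movement is added to genuinely slow
movement, and the slow (resident) state's speed mean is systematically
inflated relative to the noise-free truth — at the default Argos error mix
the inflation is tens of percent for the slowest (~0.9 km h⁻¹) state — and
spurious decoded switches inflate the switching probabilities (by ~25% for
the rarer resident-to-transit rate), while transit speeds are recovered
within a few percent. This is inherent to imputation-based inference under
location error, not an estimator defect; the test suite asserts it
explicitly.

## Spatial summaries

Management areas are simplified lon/lat boxes packaged as GeoJSON
(swappable for exact polygon boundaries): four CCAMLR statistical areas
(58.5.1, 58.4.1, 58.4.2, 58.4.3b), the proposed Drygalski MPA (allowed to
overlap the CCAMLR layer and summarized separately), and the IWC management
areas with the III/IV boundary at 70°E and IV/V at 130°E. Box assignment is
half-open — south/west edges inclusive, north/east exclusive — so meridian
boundary points assign eastward deterministically; within a category the
first containing area in west-to-east order wins. CCAMLR-category points in
no area are "Northern". Longitudes are normalized to [-180, 180); the study
polygons are dateline-free.

Per-whale rows report maximum great-circle displacement from the tagging
location, total along-track distance (with the net displacement across a
declared reporting gap added, mirroring the published convention for a
non-reporting period), location counts, and percent of locations decoded
resident — suppressed where fewer than 10 locations are available (overall
or per area). Decoded step states are expanded to locations by giving each
location the state of the step leaving it (a segment's last location
inherits its final step's state). The overall row uses the arithmetic mean
and the n-1 sample SD. Arrival time into a region is the fractional number
of days from a departure reference — by default the last fix within 100 km
of supplied coastal reference points, an operationalization of "leaving
coastal waters", which the source does not define — to the first fix inside
the region.

The published per-whale summary table is packaged as a fixture containing
only its unambiguous cells (id, sex, displacement, distance, location count,
percent resident); the per-area columns of one animal are ambiguous in the
source text and are not stored.

## Catch gridding

Catch records aggregate onto a 1x1-degree grid under the floor convention
(cells and filter windows are half-open), so grid totals exactly conserve
the filtered record totals and 2x2-degree cells are exact sums of their four
constituents. Reproducing the actual historical catch totals is out of
scope (the catch database is external); the packaged generator produces
synthetic records for exercising the stage.

## Validation scales and numerical choices

* Forward likelihood and Viterbi agree with exhaustive path enumeration
  (T <= 10, 50 random parameterizations, 1e-9).
* The smoother matches a direct joint-Gaussian conditional on a 5-node toy
  problem (1e-8) and reduces RMSE versus raw class-B fixes on simulation.
* Parameter recovery and AIC model selection run at the study's scale —
  12 tracks of ~425 six-hour steps (~5100 steps, matching the filtered
  location count) — with 20 replicates for selection and a full
  Argos-noise + imputation pipeline at m = 10 for the pooling chain. The
  switching probability Pr(transit|resident) = 0.017 is a rare event:
  ~5100 steps contain only ~60 resident-to-transit switches, so a single
  replicate's sampling error exceeds 10% relative; recovery of the
  switching probabilities is therefore assessed on the median across the
  20 replicate fits.
* Rubin-rule coverage is verified at the pooling level with synthetic
  working-scale fits of known within/between variance (40 replicates,
  m = 10), which isolates the pooling formulas from HMM sampling noise.
* Optimizer tolerances are tightened (ftol 1e-12) so refits under permuted
  inputs agree to ~1e-6 in log-likelihood; covariance matrices use central
  finite differences (step 1e-4) and pseudo-inverses, with eigenvalue
  clipping where exact observations make conditional covariances
  numerically semidefinite.

## Known limitations

* Simplified box geometries, not legal management boundaries.
* Normal (not t) Argos errors; no land masking; no duty-cycle model.
* The slow-state speed inflation under location error described above.
* Degrees-of-freedom correction for small-m pooling is optional (normal
  quantile by default); the source does not state its pooling rule, so
  Rubin normal-theory pooling on the link scale is the package's choice,
  with percentile pooling as an alternative.
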