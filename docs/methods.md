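# Methods notes

This note records the models, the parameter choices that matter, what the
synthetic data generator does and does not emulate, and the decisions taken
where the design was genuinely open.

## Synthetic SRDL generator

The generator emulates the data stream of a CTD-SRDL on a hooded seal:
Argos fixes with location-class (LC) dependent error, on-board-compressed
dive profiles (two surface points plus four at-depth inflection points),
17-point CTD up-casts every 6 h, and haul-out intervals.

**Movement.** Each animal alternates haul-outs at the deployment centre
(13.50 E, 73.86 N; 1.5 d default) with trips: directed transit toward a
prey patch (speed ~1.1 m/s, heading noise 15°), area-restricted search
(ARS) inside the patch, and return. ARS is mechanistic — the animal heads
toward random prey spots drawn uniformly in the patch at reduced speed
(2.5/dwell_factor of transit speed) with 40° heading noise — so that FPT
detection of the patches downstream is a genuine inference, not an echo of
time-stamp editing. The ARS bout length is dwell_factor × the patch
crossing time, which makes the bout's path roughly five patch radii and
lets the search genuinely span the nominal patch scale. Argos error is
drawn per fix from an LC-conditional isotropic Gaussian; default SDs
{3: 0.25, 2: 0.5, 1: 1.5, 0: 5, A: 8, B: 15} km are plausible published
magnitudes and configurable. Injected artifacts for filter validation are
LC-Z fixes (drawn from the LC mix) and isolated single-fix spikes displaced
35–50 km perpendicular to the path; along-track or adjacent displacements
are deliberately not injected because they are geometrically plausible
movement that no speed/angle filter could — or should — remove.

**Dives.** Depth and duration are class-conditional lognormals (pups
median 75 m / 4.5 min; adults ~230 m / 12–13 min), truncated at local
bathymetry (resampled when deeper, clipped as a last resort). Profiles are
U-shaped (flat bottom wiggles), V-shaped, or sloping-bottom; the last class
has a long gently sloping mid-segment that passes the drift-candidate
screen and supplies the negatives the drift classifier must learn to
reject. With probability `drift_dive_prob` a dive is a drift dive: a
long (~40% of duration) passive segment whose vertical rate equals the
condition trajectory plus N(0, 0.02 m/s) noise. The default condition
trajectory rises linearly from −0.35 to −0.20 m/s over 30 days (fattening),
within the −1.2…+0.3 m/s envelope seen in free-ranging animals. In-patch
dives carry descent/ascent rates elevated by one generator SD — the
vertical foraging signal.

**What is not emulated.** Argos error is isotropic Gaussian rather than
heavy-tailed with error ellipses; dive shape does not follow dive
physiology (no aerobic limits); the ocean fields are smooth analytic
surfaces; CTD temperature profiles are a two-layer blend. Passing tests
therefore demonstrate method correctness and recoverability under
controlled conditions, not performance on real telemetry with its
autocorrelated, non-Gaussian error structure.

## Track processing

The SDA filter drops LC-Z fixes, then iterates to a fixed point removing
(a) the worst fix whose travel to *both* neighbours exceeds 2 m/s
(both-neighbour rule first, as in the published filter description), then
(b) spikes with interior angle < 15°/25° and both legs > 2.5/5 km.
Iterating to a fixed point makes the filter idempotent by construction.

Smoothing is a continuous-time correlated random walk (integrated
Ornstein-Uhlenbeck velocity) Kalman filter + RTS smoother in a per-animal
tangent-plane projection, with per-LC measurement SDs and β, σ estimated by
Nelder-Mead maximum likelihood per track segment (segments split at gaps >
72 h). During haul-out intervals the transition matrix pins velocity to
zero and freezes position. Output is a regular 1-h track with positional
SE from the smoother covariance. The regular interval and the CTCRW
parameterization are package choices; the originating studies do not state
theirs.

Seasons: post-breeding runs from record start (tagging at breeding) to
molt onset (default July 1; per-animal override), for pups to the first
haul-out after June 15; post-molting runs to the first haul-out after
February 15. Trips: adults start at the last fix inside the 250-km disc
around the deployment centre and end at the first fix back inside
(complete) or the record end (incomplete); pup trips are season-delimited
regardless of the disc.

## First passage time

FPT uses equidistant 5-km resampling along the path (timestamps
interpolated proportionally within segments; the trailing partial segment
< 5 km is dropped). Crossing instants are linearly interpolated in
distance-to-centre on the crossing segment. Scale selection maximizes the
variance of **log** FPT over radii 5–100 km (1-km steps). The raw-FPT
variance is also computed and reported, but on tracks mixing transit with
patch dwell it grows monotonically with radius — ever more points see the
dwell — so it cannot peak at the search scale; the log transform, which is
also the originating method's standard, is therefore the selection default.
FPT points within one ARS scale of a haul-out site are removed before the
daily averaging. The 75% foraging-day quantile (type-7) is pooled across
animals by default (per-animal scope by config); a pooled scope matches
the reporting of a single threshold value.

## Transit-rate index

PCA on standardized (descent, ascent) pairs, axis-1 loadings sign-fixed
positive; the score — not the raw rates — is multiplied by the depth
weight. The weighting curve is w(d) = (d/100)^k with k = 2 by default:
the simplest smooth monotone form through the two fixed endpoints w(0) = 0
and w(100 m) = 1; the exponent is configurable because only the endpoints
and the non-linearity are fixed by the method's definition. Daily
averaging divides the summed weighted scores by the dive count by default
(Σwᵢsᵢ/n); a weighted-mean variant (Σwᵢsᵢ/Σwᵢ, zero on all-zero-weight
days) is a config switch, since the definition leaves the denominator open.

## Drift-rate pipeline

Candidate passive segments: any of the three interior profile legs with
duration ≥ 0.30 of the dive and |vertical rate| in [0.01, 1.2] m/s; the
first (descent) and last (ascent) legs never qualify. The thresholds come
from the drift-dive literature, live in config, and are exercised by the
sensitivity of the tests. Sign convention: drift rate negative = sinking.

Classification is a random forest over (duration fraction, |rate|, rate
contrast to the dive's other legs, depth span, dive duration, max depth),
trained on simulator-labelled dives — semi-supervised in the sense that
labels come from the generator's ground truth, optionally augmented with
hand labels; a dive with no candidates has probability 0 by definition.
Isolated positive-rate segments are excluded unless ≥ 2 other positive
segments from the same animal fall within ±5 days (positives are rare but
influential); all positives are flagged for review. Trips enter the spline
stage only with ≥ 1 segment per 2 days.

The per-trip smoother is a weighted cubic smoothing spline with the
penalty chosen by generalized cross-validation; weights are depth weight ×
classifier probability, zero-weight segments are dropped, and duplicate
abscissae are merged by weighted mean with summed weight (which makes the
fit exactly invariant to splitting an observation into two at half
weight). The "constrained" part is enforced by projecting predictions onto
the observed drift-rate envelope ± 0.05 m/s — a range constraint; monotone
or shape constraints are not imposed. Daily rates are evaluated at
UTC-day midpoints without extrapolating beyond the observed segment span;
the daily change is the central finite difference (one-sided at the ends).

## Environment

Bathymetry/ice/SST rasters are xarray grids (NetCDF3 via the scipy
engine); lookups are nearest-cell by default with bilinear as an option,
and the time axis (ice, SST) matches to the nearest date. Per-dive SST is
the shallowest CTD point's temperature (nominally 6 m — the implementation
takes the minimum-depth point whatever its exact depth) when a profile
lies within 3 h of the dive; otherwise time-linear interpolation between
the bracketing profiles, or the nearest profile (flagged) beyond the ends.
All daily environmental values are arithmetic means per UTC animal-day.

## Habitat models

Each daily index is modelled with Gaussian additive mixed models: cubic
regression-spline smooths of standardized bathymetry and SST (basis
dimension k = 5, sum-to-zero centred, one column dropped), optionally per
class, a class main effect, and random intercepts for animal and for trip
within animal (statsmodels MixedLM, maximum likelihood so AICs are
comparable across fixed-effect structures). The smooths are deliberately
unpenalized with a small fixed basis: the basis dimension is the
regularizer. An explicit mixed-representation penalty per by-class smooth
would add variance components that are estimated unreliably at the row
counts this package targets, while k = 5 leaves structure selection and
smooth recovery unaffected (both are exercised by recovery tests).
Parameter count for the parsimony rule = fixed effects + 2 variance
components + residual. Adjusted R² uses fitted values including the
predicted random effects. Candidate models are all subsets of the smooth
terms; selection keeps models with ΔAIC < 2 and picks the fewest
parameters, ties broken by AIC then term order. FPT can be log-transformed
before modelling by config; the default models the raw daily mean.

## Movement statistics

Trip azimuth is the initial great-circle bearing (clockwise from north)
from the trip's first point to its most distant point (ties to the
earliest); cos/sin give the N–S and E–W components. Distance and duration
are reported only for complete trips. The Rayleigh test uses the standard
approximation p = exp(√(1+4n+4(n²−nR̄²)) − (1+2n)). Mann-Whitney tests
are exact for ≤ 20 total untied observations, otherwise normal
approximation with tie correction; two-sided throughout; no
multiple-comparison correction by default (raw pairwise p-values are
reported), with correction available as a flag.

## Numerical and scope choices

- Distances: haversine on the sphere R = 6371.009 km; timestamps UTC;
  "daily" always means UTC calendar day.
- Dives are anchored at their start time for geolocation and daily
  grouping; dives shallower than 10 m are excluded by default (configurable
  `min_depth_m`), consistent with reported dive-depth ranges starting at
  10 m.
- The daily modelling join is inner on (animal, day); a full outer audit
  table with per-source presence is always written so join losses are
  accountable.
- Problem sizes in the drivers and validation experiments (3–6 animals,
  10–60 days, 20-seed recovery loops) are chosen so each experiment is a
  clear parameter-recovery exercise at desk scale; all sizes are config.

## Known limitations

- The CTCRW smoother assumes isotropic per-LC measurement error; Argos
  error ellipses and heavy tails are out of scope.
- The drift classifier is only as good as the simulated negatives; on real
  data the compressed 6-point profiles can make V-dives and drift dives
  genuinely ambiguous, and probabilities should be treated as weights, not
  verdicts.
- Range-projection is a pragmatic constraint implementation: it guarantees
  the envelope invariant but, unlike a constrained least-squares fit, does
  not redistribute the fit inside the envelope.
- AIC for mixed models is computed on the ML likelihood with a fixed
  parameter-count convention; other conventions (conditional AIC) would
  shift absolute values but rarely the selection.
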