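# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic data can show.  Everything quantitative below is
computed by the test suite or the example scripts; nothing is asserted
from memory.

## Scene model

The observer's eye is the origin of a right-handed frame: +Z up, +Y along
the road towards the approaching vehicle, +X across the road.  The road
centerline sits at x = curb gap + road width/2 = 0.64 + 1.68 = 2.32 m; the
stopping line is abeam of the eye (Y = 0); the tracked point is the
vehicle front-plane center at height 1.47/2 m.  A left-side approach
mirrors X.  With a fixed 3 s display, a comparison at speed v and
remaining TTA t must start v·(3 + t) from the stopping line and vanish at
v·t, which couples start/end distance to both task variables — the source
of the position-cue confound that the dominance analysis quantifies.

Projection is a two-step chain: a pinhole camera (default vertical FOV
55°, horizontal FOV from the 1280:1024 aspect) maps view directions to the
image plane; the image is then viewed as a flat screen spanning ≈30° × 25°
at 0.66 m, and screen positions are expressed in per-axis visual degrees
(tangent-corrected).  The chain is exactly invertible on its domain
(round-trip < 1e-6°, property-tested).  Under this honest tangent model a
2.085° world span at 50 m lands at ≈0.86–0.89° on screen; the small-angle
ratio 2.085·(25/55) gives 0.95°.  Both are "just under one degree"; the
on-screen figure is treated as a calibration check, not a fitted target,
and the FOV is configurable.

Two reference frames matter downstream and are deliberately distinct:

* **eye frame** (observer vs physical screen): saccade amplitudes and the
  detector's velocity thresholds live here;
* **world frame** (virtual scene): pursuit gain compares gaze to the
  vehicle here, by back-projecting gaze through the camera, because the
  screen compresses world angles ≈2.4× near the center.

## Synthetic observer

*Gaze.*  Per trial the eye starts on the vehicle-AOI center and tracks it
with velocity gain drawn from N(gain_mean = 0.87, 0.05).  A per-trial
anchor offset (mean 0.5° ahead, 0.7° above; SDs 1.2°/0.7°) displaces the
tracked point, producing the ~1° positional deviations and the
idiosyncratic placement that makes observers decodable.  Catch-up saccades
fire when position error exceeds a threshold (default 1°); exploratory
saccades arrive at ~0.5 Hz with amplitude ~N(1.2°, 0.3°); both use a
minimum-jerk profile of duration 20 ms + 2 ms/deg (peak velocities well
above the 22 °/s detector threshold) and a 150 ms refractory period.
Blinks are Poisson (0.1 Hz), 100–300 ms.  Tracker noise is white at
0.015° (1000 Hz reference; the per-sample SD scales with √(rate/1000) so
the spectral density — and thus every filtered analysis — is invariant to
the simulation rate).  These values were chosen once so that the default
cohort lands in the descriptive ranges typical of this paradigm (gain
0.8–0.95, ~2–3 counted saccades of ~1.2°, absolute deviations ≈1°) and
were not revisited.

*Choices.*  Each interval yields an internal estimate Σ_c w_c·z_c +
N(0, σ_int) over the four cues (speed, TTA, start, end distance) z-scored
on the 81-cell grid; the observer picks the interval with the larger
task-relevant estimate (a standard 2IFC differencing rule, so a unit-weight
observer's psychometric slope is σ_int·√2 in z units — verified within 5 %
by simulation).  A bias (default +0.15) is added to the second interval's
estimate and a 2 % lapse produces uniform guesses.  Default weights
(speed task: speed 0.9, start 0.4, end 0.25, TTA −0.2; TTA task:
TTA −0.8, end −0.5, start −0.3, speed 0.15) are **illustrative**, not
estimates from any dataset; they were set so that σ_int = 0.65 yields
thresholds of the reported order (~18 km/h, ~0.7 s) and so that the cohort
over-weights position cues relative to a single-cue ideal observer.
Trials where the comparison equals the standard on the task cue have no
wrong answer and are scored correct.

*What the generator does not emulate*: learning across blocks, head or
body movement, vergence, main-sequence kinematics beyond the duration
rule, anticipatory pursuit, and any coupling between gaze quality and
choice accuracy (the performance-model tests therefore inject their own
trial-level coupling).  Passing tests show the analysis chain is correct
and calibrated on data with this structure — not that real data satisfy
the generator's assumptions.

## Event detection

A sample is saccadic when 2D eye-frame speed exceeds 22 °/s plus a pursuit
allowance (trailing 40 ms mean speed over non-saccadic samples, capped so
the effective threshold never exceeds the 60 °/s fixup limit) or when
acceleration exceeds 5000 °/s².  The proprietary reference parser is
approximated as follows, with every choice configurable:

* velocity from central differences with a 5 ms boxcar (the hardware
  parser also applies a short velocity model; on unsmoothed 1000 Hz
  samples any realistic white tracker noise would otherwise saturate the
  acceleration criterion),
* acceleration differenced over ±2 samples of the smoothed velocity,
* the pursuit allowance is computed twice, the second pass excluding
  first-pass saccadic samples (so saccades do not raise their own
  threshold),
* runs shorter than 6 ms are discarded *before* merging events closer
  than 20 ms (merging first would let noise flickers coalesce), and
  events starting within 20 ms of the trace edge are dropped,
* amplitude is the great-circle angle between eye-frame gaze directions
  at onset and offset.

On noise-free synthetic traces the detector recovers every ≥1° event with
onsets within ~3 ms; with default noise it achieves the ≥95 % recall /
≤5 % false-positive target asserted in the acceptance suite.  Blinks are
padded invalid-pupil runs (20 ms per side, overlaps merged).  Cleaning
replaces event windows by linear interpolation (idempotent); trials are
dropped when >50 % of either interval is interpolated, and a participant
leaves a condition when >50 % of its trials are dropped.

## Gaze metrics

Angular velocity is ω_i = asin(‖u_i × u_{i+1}‖)/Δt on consecutive unit
directions.  For pursuit gain the **vector components** of the
angular-velocity axis are low-pass filtered (zero-phase Butterworth,
order 2, 10 Hz) before taking magnitudes: filtering the rectified speed
would rectify zero-mean noise into a large positive bias at the ~1 °/s
target speeds of this scenario.  Gain is the ratio of window means (not
the mean of ratios, which explodes when the target barely moves), taken
over the 2–3 s window before vehicle offset for descriptive/classification
features and over the full visible interval for the performance model.
Samples inside detected events, padded by 100 ms (the filter's ring-down),
are excluded from the averages so interpolated saccadic displacement does
not masquerade as pursuit; with this scheme a simulated gain-g tracker is
recovered within 0.02 for g ∈ [0.5, 1.1].

Deviations are signed (horizontal sign flipped for left-side approaches so
positive = ahead in the motion direction) and absolute means from the
dynamic AOI center.  The first saccade after vehicle onset (typically the
orienting movement) is excluded from counts and amplitudes.  Outliers are
flagged per observer and feature: symmetric MAD (consistency constant
1.4826, cutoff 3.5) for roughly symmetric features and a double-MAD
(separate MADs below/above the median, deviations always taken from the
overall median, cutoff 4.5) for the skewed saccade count and amplitude; a
zero MAD on a side flags nothing there.  `remove_outliers` drops whole
rows (complete cases for the classifiers); `outlier_report` counts flagged
data points, the unit in which removal rates of a few per cent are
meaningful.

## Psychometrics

ψ(x) = γ + (1 − γ − λ)·Φ((x − PSE)/σ), maximized over the binomial
likelihood with bounds γ ∈ [0, 0.05], λ ∈ [0, 0.1], PSE within the level
range, by L-BFGS-B from a 5 × 5 (PSE, σ) multistart grid (the rate bounds
create local optima).  The TTA task is fitted against −TTA so ψ increases
with "earliness"; `pse_native` maps back.  JND = (x(0.75) − x(0.25))/2 on
the full ψ including asymptotes; undefined (raised) if an asymptote blocks
a quantile.  SE/CI of the JND and the deviance p value come from parametric
bootstrap with warm-started refits (the bootstrap convention of the
standard fitting toolboxes in this area); a fit whose likelihood does not
beat a constant, or whose σ hits its upper bound, is flagged
`uninformative` and its JND `unreliable`.  Interval bias is estimated by
refitting "chose interval 2" against the interval-2 stimulus value.

## Cue dominance

McFadden R²_M = 1 − ℓ_model/ℓ_null over exact-MLE logistic fits (a
small-ridge refit, flagged, handles complete separation).  General
dominance averages the incremental R²_M of adding predictor j within each
subset size (empty set included), then across sizes — the Shapley value of
R²_M, so the values sum to the full-model R²_M to 1e-10 (asserted).  The
ideal-observer baseline adds Gaussian noise to the task cue of **both**
intervals (symmetric differencing; configurable) with per-participant SD
taken from the fitted psychometric σ.  Because the fitted σ already
reflects two intervals' noise, a matched baseline uses σ/√2 per interval.

## Task comparison and decoding

The two-condition repeated-measures MANOVA is the one-sample Hotelling T²
on paired task differences: Λ = 1/(1 + T²/(n−1)), F = ((1−Λ)/Λ)·((n−p)/p)
on (p, n−p) df — with the published Λ = 0.362, n = 14, p = 9 this
reproduces F(9,5) = 0.98 exactly.  Identical task means give Λ = 1 (T² set
to 0 without inverting the then-singular covariance).  Decoding uses an
RBF-kernel SVM (C = 1, kernel width 1/(p·Var), features z-scored with
training-fold statistics only; all configurable and logged in reports):
leave-one-subject-out for the task label, seeded unstratified tenfold for
the observer label.  Accuracy is the mean over folds; the no-information
rate is each test set's majority-class share; the binomial test is
one-sided on pooled test predictions.  Permutation tests (default 1000)
permute task labels within participant (respecting exchangeability) and
observer labels globally; p = #(permuted ≥ observed)/n_perm, reported as
"< 1/n_perm" when zero.

## Performance model

logit P(correct) = Xβ + Zu with crossed random factors (observer, the nine
comparison-speed levels, the nine comparison-TTA levels as categorical
grids), diagonal (uncorrelated) random-effect covariance, fitted by
Laplace-approximate ML.  With the spherical parametrization u = Λv the
objective is ℓ(θ, β) = loglik(v̂) − ‖v̂‖²/2 − ½ log det(ΛᵀZᵀWZΛ + I),
maximized over (θ, β) jointly (numeric-gradient L-BFGS-B, log-σ bounds
[−8, 3]) with v̂ from an inner damped Newton — the same formulation as the
reference R implementation at its default one-point quadrature, which it
matches on a shared dataset to ~1 % in estimates and <0.5 in
log-likelihood (asserted against `glmer` via Rscript).  SEs come from the
β block of the inverse joint (β, v) Hessian.  Fixed effects are z-scored
first and reported on that scale (the scaling is recorded).  The
simplification ladder tries the full uncorrelated model, then slopes for
the observer only, then intercepts only, stopping at the first
convergence and recording every attempt's log-likelihood and AIC; if
nothing converges a plain logistic fit is returned with a prominent flag.
VIF_j = 1/(1 − R²_j) from linear regressions among the fixed predictors;
rank-deficient designs raise with the aliased columns named.

## Problem sizes

Defaults were chosen as the package's own desk-scale working points: the
pipeline default simulates gaze at 100 Hz (detector thresholds are
rate-independent in physical units; 1000 Hz matches the original recording
and is one flag away), the test cohort is 10 observers × 81 trials × 2
tasks, bootstrap defaults are 200–1000 resamples, permutation-uniformity
checks use 200 replicates × 49 permutations, and the GLMM sign-recovery
check uses 50 replicates of 8 observers × 120 trials with random
intercepts.  An end-to-end default run (15 observers, 2 × 243 trials)
completes in a few minutes on one core.

## Known limitations

* The detector is a documented approximation of a proprietary parser; only
  its published thresholds are faithful.
* Pursuit-gain estimates carry a small upward bias (≈ +0.02 at default
  noise) from rectified in-band noise; it vanishes with noise-free input.
* The GLMM engine supports diagonal random-effect covariance only —
  correlated intercept/slope models (which the simplification ladder
  exists to avoid) are out of scope.
* Dominance analysis reports general dominance only, not conditional or
  complete dominance ranks.
* Real-data idiosyncrasies (drift correction, asymmetric blink artefacts,
  calibration error, head motion) are not modelled; conclusions about real
  recordings require the real recordings.
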