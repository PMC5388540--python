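# Methods

This note records the modelling choices behind `objcode`: the
procedures themselves, the defaults and why they were chosen, the
numerical conventions, and what the synthetic data generator does and
does not emulate.

## Stimulus battery and tangent-screen geometry

The battery holds 10 objects x 38 views: 8 azimuth positions (−22.5°
to +30° in 7.5° steps, elevation fixed at 0°), and, at each of the two
default azimuths (±15°), 4 sizes (15/25/45/55°; 35° is the default),
4 in-plane rotations (±20°, ±40°), 4 in-depth rotations (±40°, ±60°)
and 3 luminance attenuations (50/25/12.5%).  Per-neuron analyses use
all 8 positions plus the non-position views at whichever default
azimuth is nearer the neuron's RF center (ties resolve to −15°),
giving 23 views per object (230 stimuli); population analyses drop the
4 positions far from the RF side and align the two RF groups
position-by-position, giving 19 views per object.

Because the display sits only R = 30 cm from the eye, stimuli are
drawn under a tangent-screen projection: a point (x₂, y₂) on the
virtual screen tangent at azimuth θ maps to display coordinates
x₁ = R tan(θ+φ) − R tanθ with φ = atan(x₂/R), and
y₁ = y₂ cosφ / cos(φ+θ).  The y rule is the ratio R₁/R₂ of the
distances from the eye to the two screens along the pixel's azimuth;
it is the unique reading consistent with the θ = 0 identity.  The
inverse map is provided and round-trips to 1e−9.

The original objects are unavailable, so a procedural library of 10
grayscale shapes (clipped mixtures of soft-edged elliptical lobes)
stands in.  It matches the qualitative diversity of silhouette and
overall brightness — enough pairs are luminance-matched for the
ThLumRatio analyses to behave as designed — but not any specific
luminance histogram.  In-depth rotation of a 2-D shape is approximated
by horizontal foreshortening (cos of the angle) plus a mild
configurable shear (`DisplayGeometry.indepth_asymmetry`, default 0.2);
this is a stand-in for true 3-D pose change.

Rendering evaluates the shape at the inverse-projected location of
each display pixel, so the retinal image of a view is
azimuth-independent *by construction*: the analytic retinal sampler
(`retinal_image`) is exact (tested to 1e−12), while numerically
back-projecting a rendered display raster is interpolation-limited
(cubic resampling of the default 4 px/deg raster agrees to ~1e−2 for
the sharpest-edged shapes; tests use that tolerance).

## Receptive-field model

RF maps are 6 x 11 grids of 10°-wide cells; drifting-bar responses at
4 orientations are averaged per cell.  `RFGaussianModel.fit()` runs a
bounded least-squares fit of baseline + amplitude ·
exp(−dx²/2σx² − dy²/2σy²), seeded by weighted moments; non-convergence
is flagged, not raised.  A fit is acceptable iff R² = 1 − SSresid /
SStotal > 0.5, and RF size is (σx+σy)/2 (NaN otherwise).

RF luminance L weights the stimulus image (mean-pooled per 10° cell,
matching the bar-mapping granularity) by the *raw* map normalized to
its maximum, then divides by the full-field response, so L ∈ [0, 1]
regardless of RF shape.  RF contrast C is the SD of RF-weighted cell
luminances "inside the RF": cells within the 1-SD ellipse of an
acceptable fit, else cells with normalized raw weight ≥ 0.5 (graceful
degradation for non-elliptical maps).  The SD convention is population
(ddof = 0) and configurable; neither the boundary nor the convention
is forced by the design, so both are explicit parameters.  Neurons
enter the contrast-information analysis only if ≥ 23 conditions cover
≥ 10% of the RF weight.

## Information estimation

Spike counts are discretized into three equi-populated bins computed
on each neuron's pooled responses (quantile edges, ties to the lower
bin; heavy ties are logged).  With ~26 trials per condition this
leaves ~9 trials per stimulus and response bin, inside the validity
regime of the asymptotic bias correction
BIAS = [Σₛ(Rₛ−1) − (R−1)] / (2N ln2), which is subtracted term-wise
from every plug-in estimate.  Support sizes Rₛ, R default to naive
occupancy counts; an occupancy-inversion estimator (smallest support
whose expected occupancy under uniform sampling reaches the observed
count) is available as `support_method="bayes"`.  The two agree
whenever sampling is dense, which is the regime all shipped analyses
operate in.

The decompositions I(R;S) = I(R;L) + I(R;S′|L) and
I(R;S) = I(R;O) + I(R;T|O) are computed with the conditional term
evaluated directly (Σ P(l)·I(R;S|L=l), bias-corrected per stratum),
never by subtraction; because the conditioning variable is a
deterministic function of the condition, the chain-rule identity holds
exactly for the plug-in terms and is verified to 1e−9 on every input.
L is discretized into 23 equi-populated bins over the 230 conditions
(10 stimuli per bin).  For I(L;O), L is deterministic given the view,
so each view contributes its trial count to the (object, L-bin) table;
this keeps the bias term's sampling unit the presentation, not the
view (23 bins over 46 views alone would sit far outside the
correction's regime and overcorrect).

Permutation significance shuffles condition labels across trials 100
times (seeded) and reports the smoothed p = (k+1)/(n+1) for the number
k of null values ≥ observed — never exactly zero, and p = 1 when the
observed value ties every null draw.  Sparseness uses
S = (1 − (mean r)²/mean(r²)) / (1 − 1/n); the luminance-sensitivity
curve averages responses at the four luminance levels across objects
and max-normalizes before its sparseness is taken.

## Single-cell decoders

The binary decoder thresholds the spike count at the zero of the
Gaussian log-posterior ratio with equal priors (trial counts are
balanced by design).  The between-means root of the quadratic is
preferred; with equal variances the closed-form midpoint is used; a
vanishing variance or absent real root falls back to the midpoint with
a logged flag, and identical zero-variance distributions return an
undecidable sentinel.  Counts exactly at threshold receive half credit
to each class — deterministic and label-symmetric.  Training
means/SDs use the sample convention (ddof = 1).  Decoders operate on
raw counts, not the 3-bin discretization, since the boundary is
parameterized by count means and variances.

Separability uses 5-fold cross-validation with folds stratified within
each (object, view) condition, so every fold sees all views (the
stratification is a package choice; nothing in the design forbids it
and it removes a source of fold-imbalance noise).  Generalization
trains on one view per object (sampled independently per iteration,
1000 iterations by default) and tests the remaining views of the
chosen axis; the rotation axis pools in-plane and in-depth views.  The
parametric position analysis trains both objects at the same position
and tests 7.5/15/22.5/30° away — rightward for training positions in
[−22.5°, 0°], leftward for [+7.5°, +30°] — averaging over the eight
training positions; the size analysis averages its eight directed
train→test evaluations into large→small and small→large groups.
Performance is the mutual information between actual and predicted
labels of the accumulated confusion matrix (plus percent accuracy);
the matched chance run — object labels shuffled separately within each
transformation, identical pipeline and seeds — is subtracted from the
information metric only.

## Population decoding

Pseudo-population vectors sample trials independently per unit and
condition, without replacement, M per condition (M defaults to the
minimum available trial count capped at 25; the design leaves M open
and this maximizes data under the without-replacement constraint).
The readout is a linear soft-margin SVM with C = 1 (liblinear
squared-hinge implementation; if its iteration cap is hit the fit
falls back to a least-squares linear classifier and the result is
flagged).  Separability uses the same stratified 5-fold scheme;
generalization trains one classifier per ordered pair of train views —
all 19² = 361 combinations — and merges the 361 confusion matrices
before computing performance; the arbitrary-group control mixes
9 + 10 views of the two objects into each of two groups (50 resamples).
Chance subtraction again applies to information only, never accuracy.
Area suites run 50 subpopulation resamples per (area, N, pair) with
N ∈ {6, 12, 24, 48, 96}, and compare areas per pair with 1-tailed
Mann-Whitney tests over the resample values (one value per resample;
folds are not pooled), Holm-Bonferroni corrected within each metric's
family.

## Synthetic data generator

A unit's rate for condition S = (O, T) is
rectify(baseline + luminance_gain · L(S) + identity_gain[O] ·
(tol + (1 − tol) · m(T))), with Poisson counts over the 150 ms window.
The view modulation m(T) is frozen per unit: a lognormal draw per
transformation label (SD `view_jitter_sd`, mean 1) times the unit's
spatial RF gate evaluated at the view's azimuth.  This gives
`tolerance` a precise operational meaning — tol = 1 is a fully
view-invariant identity code, tol = 0 ties the identity signal to
specific views and, through the gate, to the RF's position — and makes
position generalization decay with distance for low-tolerance,
small-RF units.

The four shipped area profiles grade luminance gain down
(V1like 20–40 → LLlike 1.5–5 spikes/s per unit L) and identity gain
(3 → 9 spikes/s), tolerance (Beta(2,8) → Beta(8,2)) and RF size
(σ 4–8° → 12–20°) up, with RF centers near ±15° azimuth, baselines
1–4 spikes/s and 26 trials per condition.  These values were chosen
once to produce firing in the observed physiological range (a few to
tens of spikes/s) and clearly ordered functional gradients; they are
not fitted to any recording.  The generator emulates Poisson count
statistics, RF geometry and the luminance/identity/tolerance trade-off
the analyses measure.  It does not emulate trial-to-trial correlations,
adaptation or latency dynamics within the count window, non-elliptical
RFs, or realistic object-specific luminance histograms — so passing
tests demonstrate the correctness and calibration of the analysis
chain and the recoverability of generative parameters, not any claim
about real cortex.

Spike-isolation metrics (SNR, RV) are attached as given attributes and
drawn from lognormal/exponential distributions; the screening,
latency (PSTH in 10 ms bins, Gaussian smoothing SD 5 ms, first
crossing of baseline + 20% of peak−baseline) and tertile analyses
consume them exactly as they would real values.

## Problem sizes

The default verification runs use: 25–50 units per condition arm,
26 trials per condition (500 where count statistics themselves are
under test), 20–50 decoder iterations per generalization estimate,
N = 24–48 unit pseudo-populations with M = 20–25 vectors and 8–50
resamples, and 200 Monte-Carlo replicates for estimator-calibration
checks.  The acceptance script uses a 70-unit pool, 48-unit
subpopulations, 3 object pairs and 50 resamples.  All stochastic paths
take explicit seeds and are bit-reproducible.

## Known limitations

* The shape library is a 2-D procedural stand-in; in-depth rotation is
  a foreshortening approximation, not a pose change of a 3-D model.
* The first-order bias correction leaves a small residual at very low
  trial counts; analyses keep ≥ 4 trials per stimulus and response bin.
* The "inside the RF" boundary for contrast, the SD convention, and
  the Bayesian support estimator's exact form are documented package
  choices where the design left them open; all are configurable.
* Pseudo-populations deliberately destroy noise correlations; the
  package makes no claims about simultaneously recorded populations.
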