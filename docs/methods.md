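# Methods

## Signal model

The package treats the per-frame pixel sum inside a fixed rectangular ROI
around one eye as a proxy for eyelid position: the lid reflects more light
than the open eye, so a blink is a pulse whose peak marks full closure. The
proxy is assumed to be (a) monotonically related to lid position within a
blink and (b) stationary in baseline over the ~0.7 s analysis window;
illumination drift, head motion and gaze changes violate these assumptions
and are out of scope (the ROI is static, set once per recording).

Each cropped window (0.25 s before to 0.4625 s after the peak; 60 + 111 + 1
= 172 samples at 240 fps — "0.4625" is chosen so the post-window rounds to
exactly 111 frames) is min–max normalized to [0, 1] with 1 at the peak.
This makes the smoothing parameter transferable across light levels and
every downstream feature invariant to positive rescaling of the raw
intensity (verified to 1e-9 in the tests). A `maxdiv` normalization
(divide by the window maximum) is available as a config option.

## Smoothing spline

The position proxy is the natural cubic smoothing spline minimizing

    p · Σ_i (I_i − s(t_i))² + (1 − p) · ∫ (s'')² dt ,

with knots at the sample times and p = 0.99996 by default, t in seconds —
the MATLAB-`csaps` convention where p weights the residual. The solver is
the classical Reinsch/Green–Silverman banded system (second-difference
matrix Q, penalty matrix R; interior second derivatives solve
[R + λ QᵀQ] γ = Qᵀy with λ = (1−p)/p, then s = y − λQγ), O(n) per window.
p = 1 reproduces the data exactly; p = 0 degenerates to the least-squares
line. Tests verify the fit against a direct dense minimization of the same
objective and against `scipy.interpolate.make_smoothing_spline` (an
independent implementation of the equivalent objective with
λ = (1−p)/p) to 1e-8.

Note on units: with seconds on the abscissa, λ = 4·10⁻⁵ smooths at a
~0.05 s length scale. This is a *deliberate* amount of smoothing for blink
data — it is what keeps second differences of a 172-sample noisy window
usable as an acceleration estimate — and it measurably rounds the power
extrema (the mean |P̂(t1P)| sits well below 1 while the global extremum
|P̂(t3P)| pins at 1), which is the behaviour the feature catalogue expects.

## Derivatives, power and landmarks

Velocity and acceleration are forward differences (v: N−1 samples, a: N−2),
each assigned to the left sample time; power per unit mass is P = v·a on the
common range. All three are also stored normalized by max |·| (v̂, â, P̂),
with divisors retained for de-normalization.

While the eye is open the muscles develop no net power, so P̂ ≈ 0 outside
the blink. A well-formed blink traces four sustained P̂ excursions with
signs (+, −, +, −): closure drive, closure brake, opening drive, opening
brake. The landmark locator:

- thresholds |P̂| at `zero_tol` (default 1 % of the maximum) sustained for
  `sustain` (default 3) samples, ignoring shorter blips and merging
  same-sign runs split by dips ≤ 2·sustain samples;
- requires exactly the (+, −, +, −) pattern around the global |P̂|
  extremum, else the blink is rejected (`MalformedBlinkError`) and logged —
  rejected, never clamped;
- reports the blink start t0 and end t8P as sub-sample crossings of the
  tolerance level, and the three interior zero crossings (t2P, t4P, t6P) by
  linear interpolation between samples; extremum times (t1P, t3P, t5P, t7P
  and the acceleration landmarks t1a, t2a, t3a) stay at sample resolution,
  because an extremum's sub-sample position is not well defined on a flat
  apex. All times are shifted so the blink starts at zero.

A fourth acceleration landmark (the opening-phase braking minimum) is not
extracted: that brake is not reliably expressed in the acceleration curve,
only in the power curve (t7P/t8P cover it).

## Features

The canonical 29-feature order is frozen in `FEATURE_NAMES`: eight power
landmark times; |P̂| at the four power extrema; four work integrals; three
acceleration landmark times and magnitudes; three impulse integrals; |v̂| at
the two power zero-crossings of maximum speed; the displacement fwhm w; and
the mean-velocity ratio S. Magnitudes are read on the sample grid at the
landmark indices and stored as absolute values.

Work and impulse are rectangle-rule sums (W = T·Σ P̂, J̌ = T·Σ â over
t_c ≤ t_i ≤ t_d). As *features* they are expressed with the frame period as
the time unit (i.e. the plain sample sums, "a.u."): the integral of a unit
curve over k frames is k, which puts W(0→t2P) near 8 and J̌(0→t2P) near 13
for physiological blinks rather than values of order 0.03. fwhm measures the
width at baseline + half the pulse height, with the open-eye baseline
estimated as the mean of s before t0 and sub-sample crossing interpolation
on both flanks.

Two numerical properties worth knowing:

- the rectangle sum of forward-difference power telescopes to
  ½(v_N² − v_0²) − ½Σ(Δv)²; the second term is an O(T) bias shared by any
  implementation at the camera rate. The synthetic ground-truth oracle
  therefore predicts features *at the camera grid* (see below), and the
  discrete impulse sum telescopes exactly to a velocity difference, which is
  why J̌ converges faster than W;
- sample-grid magnitude readings can miss a sharp extremum apex by up to
  (T/2)²/width²; this is a property of the method at 240 fps, not an
  implementation artifact.

## Segmentation

Peaks are found on a lightly smoothed copy of the trace (moving average,
5 samples — the raw trace is never modified) with
`scipy.signal.find_peaks`, requiring prominence ≥ 50 % of the signal range
above the median baseline and ≥ 0.5 s separation; both thresholds are
config keys. Each peak index is refined by the vertex of a parabola fitted
over ±6 samples, which localizes noisy apexes far better than an argmax.
The localization precision is still limited by apex curvature: a blink that
holds the eye closed has a plateau where samples differ by less than the
noise, so "the" peak sample is only defined to ~±2 samples at 2 % amplitude
noise for flat-topped waveforms. This is harmless downstream — all features
are invariant to shifting the crop window.

Cropping discards blinks whose window leaves the trace (`truncated`) and
both members of any pair of peaks closer than the window (`overlap`);
discards are logged with reasons, and segments + discards always account
for every detected peak.

## Synthetic data

The generator models a blink as the difference of two logistic ramps:
baseline + A·[σ((t−μ_c)/τ_c) − σ((t−μ_o)/τ_o)], with the rise centred half
a closure-duration before the peak and the fall half an opening-duration
after, τ = duration/sharpness. Defaults: closure 0.15 s, opening 0.25 s
(closure roughly twice as fast as opening), sharpness 10, amplitude 400 on
a baseline of 1000 (arbitrary camera counts), 2 % amplitude Gaussian camera
noise, exponential inter-blink intervals with mean 6 s floored at the crop
window length, 20 s recordings at 240 fps. Populations draw per-subject
parameters with 15 % lognormal inter-subject spread; trials of one subject
jitter parameters by 8 % (fractional sd). These levels reproduce the
qualitative identification regime of real blinks — LDA on the raw per-blink
features identifies 26 subjects at ~45 % CIR, rising to ~100 % for 25-trial
averages — without claiming to model tear-film optics, partial blinks,
gaze-dependent reflectance or illumination drift. Passing tests on this
generator therefore demonstrate correctness of the computation chain and
the statistical machinery, not performance on any particular camera.

Ground truth for a synthetic blink is computed on a 100× oversampled grid:
the analytic curve is smoothed with the density-equivalent roughness weight
(λ_dense = oversample·λ, so the dense fit approximates the same continuum
smoother as the 240 fps fit), landmark times are located at dense
resolution, and the feature vector an ideal pipeline should output is
assembled from the continuum curve resampled at the camera grid. Noiseless
pipeline runs match this oracle to ~10⁻⁵ on features and to < 1 sample on
all landmark times.

## Biometrics

β-mean sets draw, per subject, `n_boot` (default 100) *distinct* sorted
β-subsets of the subject's trials uniformly at random and average them —
feature-vector averaging by default; waveform averaging (average the
cropped windows, re-extract) is available and recorded in output metadata.
Requesting more subsets than C(b, β) raises an error rather than silently
duplicating.

Classifiers: LDA (SVD solver, no covariance inversion, hence robust to
singular scatter), QDA (ridge retry on singular covariance, logged), KNN
(k = 5, Euclidean, z-scored with training-fold statistics only) and a Gini
classification tree (no depth cap); k and tree settings are config keys
since distance and tree methods are scale- and hyperparameter-sensitive.
Cross-validation is subject-stratified 10-fold (every subject represented
in every fold within one row) or leave-one-out; CIR = 100·trace(confusion)/
Σconfusion. Every report is reproducible from (dataset, classifier, scheme,
seed).

Forward selection greedily adds the feature minimizing the 10-fold
misclassified count with folds frozen per run, breaks ties toward the
lowest canonical index, and stops when no candidate strictly decreases the
loss. Selection-rate profiles simply count per-feature appearances across
repeated runs.

## Statistics

Per-feature mean and sample standard deviation use the B−1 denominator;
coefficients of variation are computed overall and per subject (same
denominator convention), with a NaN marker where a mean is zero. Boxplot
normalization expresses each value as a fractional deviation from the
feature mean; quartiles use the inclusive median-of-halves (Tukey hinge)
convention. The low-variability discard drops canonical features 10, 21
and 26 by default — the three normalized magnitudes that sit at their
ceiling of ~1 in almost every blink and therefore carry no identity — and
the indices are configuration, not hard-coded behaviour.

## Problem sizes and limitations

The test suite and the acceptance script run entirely on synthetic data:
the full study geometry (26 subjects × 74 trials = 1924 blinks) is
generated and processed in a few seconds, and the bootstrap/CV experiments
use 100 constructed blinks per subject as in the feature-averaging design.
Known limitations: no eye detection/tracking (the ROI is given); no
compensation of illumination or distance changes; verification-mode
biometrics (impostor ROC) is out of scope; and the KNN/tree results depend
on hyperparameters that identification studies rarely report, so LDA is the
classifier whose behaviour is most directly comparable across datasets.
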