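# Methods

## Signal model and preprocessing

Each trial carries one surface-EMG channel sampled at 1 kHz and one 3-axis
gyroscope at 100 Hz, recorded over 3–7 s around a single passive elbow
stretch of 120–140°.  The EMG is band-passed 20–450 Hz (4th-order
Butterworth) and the gyroscope low-passed at 10 Hz (2nd-order Butterworth),
both applied forward–backward (`filtfilt`, reflective padding of 3× the
filter order) so the net phase is zero — onset timing must not be skewed by
filter delay.  The angular-speed magnitude is the per-sample Euclidean norm
of the three filtered axes; stretch direction is deliberately discarded, so
flexor and extensor sessions are processed identically.

Onsets are found by amplitude thresholding against the pre-stretch
baseline (first 0.5 s): a run of at least `min_run` seconds strictly above
`baseline mean + k·SD` (k = 3 by default) declares the event.  Two
channel-specific refinements matter in practice:

* **EMG.**  The detection envelope is full-wave rectification followed by a
  50 ms moving RMS.  The threshold SD is taken from the baseline *signal*,
  not the envelope: smoothing shrinks the envelope's own SD so far that
  3× it sits inside the noise and false onsets dominate.  `min_run` is
  25 ms.  A detected onset outside the movement window is discarded.
* **Speed.**  Movement must outlast 0.3 s (a physiological stretch), since
  the 10 Hz low-passed noise is autocorrelated over tens of milliseconds
  and brief excursions would otherwise qualify.  The threshold crossing is
  then walked outward to the baseline noise floor (mean + 1 SD of the
  baseline speed) so the slow tails of the constant-jerk profile are kept;
  without this the mean stretch speed is biased high by 3–8 %.

Automated QC replaces manual inspection of contaminated segments: a trial
fails with a machine-readable reason when no movement is found
(`no_movement`), the stretch lasts under 0.3 s or over 10 s
(`bad_duration`), the EMG baseline SD exceeds 0.5 mV (`emg_saturation`),
or ≥ 5 % of EMG samples sit at the clip level of 4 mV (`clipping`).

## Lambda model

The per-trial DSRT is the trapezoidal integral of the angular speed from
movement onset to the EMG onset mapped onto the 100 Hz time base (nearest
sample); the per-trial velocity is the mean speed over the movement window.
DSRT is a *traversed* angle from stretch start, not an absolute elbow
angle — consistent with the 120° fallback equalling the guaranteed range of
motion.  The per-subject fit is closed-form OLS.  "95 % confidence
interval" outlier exclusion is implemented as the 95 % prediction interval
for individual observations under the initial fit, one pass, one refit —
exclusion cannot cascade.  With fewer than 3 points, or zero residual
variance, no exclusion is attempted.

The fallback rule: when the fraction of QC-passed trials with a detected
EMG onset is not strictly greater than 0.5 (configurable), the subject is
treated as lacking a typical evoked response and TSRT = 120°.  A 50/50
session therefore takes the fallback path.

## Kinematic model

The stretch window is split at the speed maximum (earliest sample on a
plateau) into stages t₁ and t₂.  The reference acceleration is two isoceles
triangles — constant jerk forces piecewise linearity; symmetry within each
stage is the minimal further assumption — with first-stage peak
acc₁ = 4000 °/s² and second-stage peak acc₂ = acc₁·t₁/t₂ so the areas
cancel.  On the discrete grid the negative lobe is rescaled by an O(h²)
factor so the trapezoidal integral of the emitted series is exactly zero.
The reference angle is the double trapezoidal integral, scaled to the
actual range of motion (trapezoidal integral of the measured speed, origin
at zero traversed angle); the same scale is carried through acceleration
and velocity, keeping the triplet exactly consistent under the trapezoid
rule — numerically differentiating the scaled angle instead reproduces the
same curves to O(h²) but breaks the zero-net-velocity identity at the
window edges.

Per eligible trial (QC-passed, stretch duration 1–2 s; both stretch
directions pooled) the biomarkers are the Pearson correlations of actual vs
reference angle, speed (speed compared directly, acceleration as central
differences of the measured speed) and the median frequency of the actual
acceleration: mean-detrended raw periodogram over the stretch window only,
DC bin excluded, half-power point located by linear interpolation between
bins.  Per-subject biomarkers are arithmetic means over eligible trials.

## Calibration, SVR and evaluation

MAS grades map to 0, 1, 1.5, 2, 3.  The lambda method calibrates TSRT by
simple OLS, the kinematic method the four biomarkers by multivariate OLS;
predictions are not clipped to [0, 3] (the fused scores' regression line on
true grades, slope ≈ 0.93, intercept ≈ 0.07 on the default synthetic
cohort, supports reading them directly as grades).

The fusion method is ε-insensitive SVR on the 5-dimensional feature vector
with an RBF kernel, C = 30, ε = 0.09 and kernel parameter σ = 0.007.  Two
conventions for σ are supported: the default reads it as an inverse squared
length scale, κ(x, x′) = exp(−σ‖x−x′‖²) (the libsvm `gamma` convention);
`kernel_form="bandwidth"` reads κ = exp(−‖x−x′‖²/(2σ²)).  The default was
chosen because it is the only reading under which σ = 0.007 yields a
non-degenerate kernel on these features: under the bandwidth form the
kernel matrix collapses to the identity, every held-out subject receives
the bias constant, and the fusion method cannot function.  Features are
z-scored by default with statistics from the training fold only — the
standard scaling step of the libsvm workflow.  Without it the TSRT axis
(range ~110°) dwarfs the kinematic features (range < 0.2) and the kernel
degenerates to a narrow one-dimensional smoother that collapses to its
bias for extreme subjects; with it the fused method's LOOCV MSE drops
below both single-model methods on 17–20 of 20 synthetic cohorts,
reproducing the expected ordering (fusion < lambda < kinematic).  Both
switches are config-exposed and tested.  The dual is solved by libsvm
(scikit-learn) with a tight stopping tolerance; predictions are computed
from the stored dual coefficients, support vectors and KKT bias, and the
test suite checks the dual against an independent dense-QP solve.

Evaluation is leave-one-out cross-validation over subjects; the reported
error is the mean of squared differences between held-out scores and
numeric grades (the defining formula of mean square error).

## Synthetic cohorts

The generator emulates the study protocol: per subject 15–20 trials with
peak velocities spanning 60–260 °/s (so the DSRT regression is
well-conditioned and several stretches land in the 1–2 s window), range of
motion uniform in 120–140°, a 1 s pre-stretch rest for baselines, total
trial length clipped to 3–7 s.  The stretch itself is symmetric
constant-jerk.  Disease enters through grade-conditional parameters:

| grade | TSRT mean ± SD (°) | severity gain | notes |
|-------|--------------------|---------------|-------|
| 0     | 120 (fixed)        | 0.03–0.08     | reflex gated below 250 °/s |
| 1     | 72 ± 13            | 0.12–0.18     | |
| 1+    | 55 ± 13            | 0.20–0.26     | |
| 2     | 42 ± 13            | 0.30–0.36     | |
| 3     | 28 ± 10            | 0.42–0.48     | |

The EMG burst (20–450 Hz amplitude-modulated noise, 50 ms rise, amplitude
0.08–0.26 mV over a ~0.01 mV baseline) starts when the traversed angle of
the noise-free profile crosses DSRT(v̄) = TSRT_true + slope·v̄ (slope
uniform in −0.4…−0.15 °/(°/s)) plus a per-trial jitter (SD 3° by default);
no burst is emitted when that angle exceeds the range of motion.  The
severity gain scales band-limited (2–15 Hz) zero-net-velocity Gaussian
fluctuations added to the stretch acceleration; the per-grade gain
intervals are disjoint, so the gain is non-decreasing in grade across any
cohort.  Gyroscope measurement noise is 0.07 °/s RMS per axis (consumer
MEMS noise density over a 50 Hz bandwidth).

The within-grade TSRT SD (13°; 10° for grade 3) and the gain ladder were
set so a 24-subject cohort reproduces the qualitative biomarker structure
the framework expects: TSRT–grade correlation ≈ −0.93 overall and ≈ −0.8
among spastic subjects, kinematic-biomarker correlations negative with the
acceleration channel strongest and the angle channel weakest, acceleration
MDF positive.  These defaults are the study conditions of the test suite
and are not tuned per test.

What the simulator does *not* model: forward biomechanics (torque, muscle
dynamics), the pause-and-return half of each trial, accelerometer or
magnetometer channels, electrode artifacts (ECG bleed-through, motion
artifacts), or absolute joint angles.  Passing tests therefore demonstrate
the pipeline's correctness and its statistical behaviour under the stated
generative assumptions, not clinical performance on recorded patients.

## Numerical choices and degenerate inputs

* Trapezoidal quadrature throughout; 10× finer Riemann sums serve as test
  oracles.
* Speed-maximum ties break to the earliest sample.
* Zero-variance predictors, rank-deficient designs (offending columns
  named), zero-variance spectra, degenerate stage durations and empty
  sessions raise errors rather than propagate NaNs.
* A subject whose feature extraction fails (e.g. no 1–2 s trial) is
  excluded from LOOCV with a logged reason; the pipeline continues.
* Problem sizes in the test suite — 24 subjects × 15–20 trials per cohort,
  20 replicate cohorts for the ordering property, 20 subjects for threshold
  recovery — were chosen to keep the full suite around half a minute while
  leaving the statistical assertions comfortably away from their
  thresholds.
* The threshold-recovery experiment draws TSRT in 40–90° with slopes
  −0.3…−0.15 so DSRT stays positive over the protocol's velocity span:
  outside that regime the reflex fires at movement onset (floor censoring)
  and a linear threshold model is no longer the data-generating truth.

## Known limitations

* TSRT recovery degrades for subjects whose thresholds censor at zero
  within the tested velocity range (severe spasticity with steep
  velocity dependence); the lambda model itself is misspecified there.
* The kinematic method's multivariate OLS can extrapolate wildly for a
  cohort's most atypical subject (large LOOCV MSE in occasional
  replicates); the fused SVR is robust to this and is the recommended
  score.
* The angle-curve correlation is a weak discriminator (integration smooths
  the severity fluctuations); it is retained for completeness.
* Median-frequency estimates use short windows (100–200 samples), so bin
  resolution is 0.5–1 Hz.
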