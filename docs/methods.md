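# Methods

## Coordinate convention and the hip-angle sign ambiguity

All landmark input follows the pose-estimator standard: normalized
coordinates with origin top-left and **y increasing downward**, each
point carrying a visibility confidence in [0, 1]. The fixed vertical
reference for the hip angle, (0, −1), therefore points *up-image*.
Under the raw arccos formula (`convention="raw_eq1"`) an upright thigh
(knee below hip) reads 180°, and flexion decreases the value. The
`"flexion"` convention reports 180° − raw, so 0° is upright posture and
the value grows with flexion — the quantity a clinician reads off a
goniometer. Both are exposed because source systems differ in which one
they log; every sign question in a 2D pipeline traces back to this
choice, so it is a required, documented parameter rather than a hidden
default. For the same reason, Bland–Altman differences are fixed as
**algorithm − clinical** throughout: a negative bias always means the
algorithm under-reads the goniometer.

When frame pixel dimensions are available, coordinates are mapped to
the aspect-corrected plane (x·width, y·height) before vectors are
taken; angles measured in raw normalized space are distorted for
non-square frames. Without dimensions the raw coordinates are used and
a warning is logged.

Knee and ankle angles are relative angles between body segments and are
invariant to rotation, translation, and uniform scaling of the frame
(fuzz-tested); the hip angle, referencing the fixed vertical, is
invariant only to translation and scale. z-coordinates in input files
are ignored — this is a strictly 2D (sagittal-plane) pipeline.

## Missing data

A landmark counts as missing when absent or when its visibility falls
below 0.5 (configurable; the conventional confidence midpoint). Missing
runs are filled per coordinate by linear interpolation in *timestamp*
between the bracketing valid samples; leading/trailing runs, having no
bracket on one side, are held at the nearest valid value. Filled values
therefore always lie inside the bracketing interval, and the operation
is idempotent. Landmarks with fewer than two valid frames abort with an
error rather than fabricating a trajectory. Coincident landmarks
(zero-length segment vectors) indicate tracking failure; the frame is
skipped and logged, never silently reported as 0°.

## Resampling and filtering

Capture hardware in this setting delivers a variable 15–20 Hz frame
rate, while a fixed-cutoff digital filter needs a constant sampling
rate. Angle traces (not landmark coordinates — smoothing operates on
the quantity of interest) are linearly resampled onto a uniform grid at
the **median observed frame rate** by default, which minimizes
interpolation distortion; an explicit rate can override this.

Smoothing uses a 4th-order Butterworth low-pass with a 6 Hz cutoff, the
biomechanics convention: physiological flexion-extension lives well
below 2 Hz, landmark jitter well above. Two modes:

* `zero_phase` (default) — forward–backward filtering, no phase lag,
  squared magnitude response (gain 0.5 at the cutoff instead of the
  single-pass 1/√2). Offline analysis should not time-shift peaks, so
  this is the default.
* `causal` — a single forward pass initialized at the DC steady state
  of the first sample, mirroring what a streaming (real-time overlay)
  deployment applies. Gain at the cutoff is the half-power 1/√2.

Zero-phase edge handling uses Gustafsson initial conditions
(`scipy.signal.filtfilt(method="gust")`), chosen over edge padding
because it makes the forward–backward and backward–forward passes agree
exactly: the operator is then precisely time-reversal symmetric and
linear (both properties tested at 1e-8), where padded variants are only
approximately so (~1e-4 on broadband input). Series must be longer than
3·(order+1) samples to filter. A degenerate filter request
(cutoff ≥ Nyquist) is rejected at construction.

## Repetition segmentation and ROM

The validation protocol repeats each exercise three times and uses the
mean value. Repetition peaks are local maxima with prominence
≥ 10° and peak-to-peak separation ≥ 1.0 s (both parameters exposed);
the defaults separate physiological repetitions from residual jitter at
15–20 Hz without assuming a repetition count. Repetition bounds are the
minima between consecutive peaks (series edges outside). The summary
value `rom_deg` is the arithmetic mean of per-repetition peaks, so it
never exceeds the global peak, and segmentation is invariant to
constant offsets.

## Agreement statistics

ICC(A,1) follows McGraw & Wong (1996): single-measure, two-way model,
absolute agreement, from the ANOVA mean squares

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),

k = 2 raters. The 95% CI uses the F-based procedure with Satterthwaite
degrees of freedom for the column/error combination evaluated at the
point estimate; bounds are clipped to [−1, 1] (an ICC is bounded, and
the unclipped small-sample lower bound can fall below −1). The p-value
tests ICC = 0 via F = MS_R/MS_E on (n−1, (n−1)(k−1)) df. With zero
residual variance the interval degenerates at the estimate. The
implementation is cross-checked in the test suite against an
independent mean-squares computation and against pingouin's ICC(A,1)
row (agreement to 1e-9; pingouin's unclipped, 2-dp-rounded CI bounds
matched after clipping). The consistency form ICC(C,1) exists only as a
test oracle for the property that a constant one-rater offset lowers
absolute agreement but not consistency.

Bland–Altman: bias = mean difference, limits of agreement
bias ± 1.96·SD (n−1 denominator); no CI on the LoA is reported.
Proportional bias is the OLS slope of differences on pair means with
its two-sided p. Error-vs-covariate regressions take either
|algorithm − clinical| or the signed difference and report the OLS
slope, p, R², plus Spearman's rho. Spearman p-values use the
t-approximation with midrank ties by default; an exact permutation p is
available for n ≤ 10 where the t-approximation is poorest.

Published agreement studies in this area occasionally print LoA
intervals that are not symmetric about the stated bias, or restate
biases with flipped signs between sections; the fixed
algorithm − clinical orientation here is the guard against that class
of ambiguity.

Cohort summaries report n, per-column mean (2 dp)/min/max, and patient
counts by procedure (THA vs TKA), with a bilateral replacement counted
once under its procedure. The bundled 14-patient table reproduces
mean months-since-surgery 7.14 (range 1–60), 9 THA and 5 TKA.

## Synthetic data

`simulate_motion` poses a sagittal-plane chain — hip fixed at
(0.45, 0.35) in a square 1080×1080 frame; thigh 0.22, shank 0.20, foot
0.07 in normalized units, plausible on-screen proportions for a
full-body ~2.5 m capture — driven by a raised-cosine flexion profile
reaching `peak_deg` once per repetition. The raised cosine is C¹-smooth
and spectrally concentrated far below the 6 Hz cutoff, so the filter
passes it essentially unchanged and recovery tests isolate the effects
of the degradations rather than of smoothing. Knee simulation keeps the
thigh vertical and swings the shank; hip simulation rotates the whole
straight leg (the foot is held at 90° to the shank in both). The frame
is square so that aspect correction is a pure scale and the analytic
ground truth is exact — verified to 1e-6 degrees against angles
recomputed from the generated landmarks.

Degradations: i.i.d. Gaussian noise per coordinate (default study-like
value 0.003 normalized units ≈ 3 px at 1080), Bernoulli visibility
dropout, and frame-interval jitter (default fraction 0.15 around a
nominal 18 Hz, spanning the 15–20 Hz capture band). The generator does
**not** emulate the structured, pose-dependent error of a real pose
estimator (limb self-occlusion, depth ambiguity, lighting), so passing
recovery tests demonstrates correctness of the processing chain, not
field accuracy of any particular pose model.

`simulate_two_way_table` draws paired measurements from
x_ij = μ + subject_i + offset_j + e_ij with the clinical/algorithm
offsets at ∓offset/2; the implied population
ICC(A,1) = σ_s² / (σ_s² + offset²/2 + σ_e²) is echoed in the output
metadata, enabling parameter-recovery and CI-coverage checks at the
study's own sample size (n = 14).

All randomness in every generator flows from a single integer seed.

## Problem sizes

Validation batteries use 500 simulated tables for ICC recovery/coverage,
1,000 null simulations for the proportional-bias type-I error, 10⁴
pairs for Bland–Altman recovery, 1,000 random frames for geometric
invariances, and 20 seeds for end-to-end ROM recovery — sizes at which
the Monte Carlo error is comfortably below each tolerance while the
whole suite runs in seconds.

## Known limitations

2D projection only: out-of-plane motion biases all angles, and the hip
angle has no pelvis reference, so trunk lean masquerades as hip
flexion. No gait-event detection, no velocity/acceleration metrics, no
repeated-measures extension of the agreement statistics, and no
multiplicity adjustment across joints.
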