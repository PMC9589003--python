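# Methods

## Scope and data model

The package consumes per-frame 2D pose output in the OpenPose BODY25 dialect
(25 joints × (x, y, confidence), image pixels, y downward, 0-based frames)
or an equivalent flat CSV, and produces trait-score regressions evaluated by
pooled out-of-fold statistics. The analysis unit is a `GaitSegment`: a
face-toward, MidHip-centred, smoothed, 75-frame (3 s at 25 Hz) window of the
24 retained joints. All downstream feature definitions are fixed functions
of this segment, so two implementations agree iff their segments agree.

## Preprocessing

- **Missing keypoints.** Joints with confidence below `min_conf` (default
  0.1) are linearly interpolated per channel over time; leading/trailing
  gaps take the nearest valid value and filled points get confidence
  `min_conf`. A joint missing in more than half the frames aborts that
  participant — interpolation over such gaps would fabricate kinematics.
  These thresholds are conservative defaults; acquisition with a visible,
  unobstructed walker rarely triggers them.
- **Facing selection.** If per-frame facing labels exist they are used
  verbatim. Otherwise the heuristic marks frames where the apparent torso
  length (Neck–MidHip distance, moving-averaged over 1 s) has positive
  slope, with the slope estimated over a centred 1-s baseline: a per-frame
  gradient is dominated by keypoint jitter (px-level noise against a
  sub-pixel per-frame trend), whereas the 1-s baseline gives a comfortable
  signal-to-noise margin for any realistic approach rate. Intervals shorter
  than the target segment (plus the smoothing loss) are discarded; the
  longest interval is analysed.
- **Centring.** MidHip coordinates are subtracted per frame and the MidHip
  dropped, making everything downstream translation-invariant. No scale or
  view normalisation is applied beyond this.
- **Smoothing.** The 5-tap binomial kernel [1, 4, 6, 4, 1]/16 applied as a
  forward window with no padding; each pass shortens a series by 4 frames.
  A `centered` alignment option exists but produces identical values — for
  a symmetric kernel the alignment only relabels which frame an output
  sample belongs to, and the subsequent centre-crop ignores labels.
  Smoothing runs after centring; since the centred MidHip is identically
  zero the order is immaterial for the reference joint.
- **Length standardisation** is a centre-crop to 75 frames, never a
  resampling, preserving native 25 Hz timing. A warning is emitted when the
  estimated cycle length implies fewer than 4 gait cycles in the window:
  4 cycles in 3 s requires a stride rate of ≥ 1.33 Hz, faster than typical
  comfortable walking (≈ 0.8–1.1 Hz), so the condition is advisory rather
  than enforced.
- **Cycle length** is estimated as twice the lag of the first prominent
  positive autocorrelation peak (> 0.3) of the mean-removed ankle–ankle
  horizontal distance, which peaks twice per stride; NaN when no peak
  qualifies.

## Feature conventions

Statistic estimators are frozen as: population variance (divisor n),
moment-based skewness m₃/m₂^1.5 and excess kurtosis m₄/m₂² − 3 (both 0 for
constant series), RMS = √(Σx²/n), absolute energy Σx², coefficient of
variation √m₂/mean (0 when |mean| < 1e−12). Angles are radians in [0, π]
(arccos of the cosine clamped to [−1, 1]); inter-joint distances are
per-axis absolute differences, so every distance channel is nonnegative.
Canonical feature names (`td_raw_j03_x_max`, `td_dist_D7_y_rms`,
`td_angle_A9_mean`, `fd_j11_x_D2_energy`, …) are stable across runs and
enumerated by `canonical_feature_names()`; `feature_dictionary()` maps each
name to its family, source indicator and statistic.

The wavelet stage uses orthonormal Haar filters (coefficients 1/√2), chosen
over the unnormalised variant because orthonormality yields an exact energy
decomposition (Parseval) on dyadic lengths — a strong test surface. The
default 75-frame segment is not dyadic; boundaries use half-sample
symmetric padding (PyWavelets `symmetric`), under which per-band
reconstructions still sum to the input within 1e−8 relative error. Band
coefficient-array lengths for 75 frames are 38/19/10/5/3 (D1–D5) and 3 (A5)
under this padding choice.

## Synthetic walker

The generator emulates the target acquisition: 25 Hz, 2-minute bouts, the
walker approaching the camera for the first half (facing label "toward",
image scale growing at `approach_rate`) and receding for the second.
Kinematics are a minimal sinusoidal limb model, not a biomechanical one:
thigh/shank angles oscillate at the stride frequency with the legs in
antiphase, arms antiphase to ipsilateral legs, constant elbow flexion, a
head bob at twice the stride frequency, and a small fixed inward leg lean
that cancels the stance-width offset so the ankle separation peaks twice
per cycle (as it does in real frontal-view gait). Perspective is an
isotropic scale proxy, keypoint jitter is i.i.d. Gaussian, and confidences
are uniform in (0.3, 1.0].

Defaults (per-walker draws): stride frequency U(0.8, 1.2) Hz, arm-swing
amplitude U(0.15, 0.55) rad, stride amplitude U(0.35, 0.75) rad, hip-to-neck
scale U(150, 250) px, head bob U(1, 4) px, approach rate 0.01 /s, keypoint
jitter SD 2 px (the few-pixel scale typical of 2D pose estimators). The
planted trait is y = β₀ + β_arm·arm + β_leg·stride + ε with β = (0, 10, 10)
and ε ~ N(0, 0.8²), then affinely rescaled so the cohort sample mean/SD are
exactly 31.40/4.55 (a realistic self-esteem marginal). Under these defaults
the correlation between the noiseless linear predictor and the trait is
≈ 0.9 — a moderate-noise regime in which recovery is hard but achievable.
The trait depends only on angular amplitudes, never on image scale, so a
pipeline that recovers it must read kinematics rather than apparent size.

What the simulator does **not** emulate: soft-tissue and footwear dynamics,
occlusion and left/right identity switches, true projective geometry,
camera distortion, within-bout gait variability, and any nonlinear or
non-additive trait structure. Passing the recovery surfaces therefore shows
the pipeline is correct and well-calibrated, not that real-world trait
correlations of any particular size are attainable.

## Modeling

Features are z-scored with moments fitted on training data only
(zero-variance columns dropped with a warning). Forward selection greedily
adds the feature that most improves the pooled k-fold CV Pearson r of the
candidate set, stopping at `max_features` (default 10) or when the best
improvement falls below `tol` (default 0.01 — below roughly one
fold-resampling standard error of a correlation at these sample sizes,
smaller gains are noise and admitting them invites overfitting). Ties break
toward the smaller canonical column index; everything is deterministic
given the seed. For linear regression the per-candidate scan is computed in
closed form by residualising y and all candidates on the selected design
(Frisch–Waugh), which is numerically identical to per-candidate refits
(tested) and makes nested selection over 2,472 features tractable.

Regressor defaults, exposed in config: OLS; GP with constant × RBF +
white-noise kernel (noise variance floored at 1e−6, target-mean
normalisation); random forest with 100 seeded trees; SVR with C = 1,
ε = 0.1, kernel scale 1/(n_features · Var(X)), polynomial degree 3.

Evaluation is k-fold (default 10) with a seeded shuffled partition and no
stratification; out-of-fold predictions are pooled and scored once: Pearson
r (overall and per subgroup; subgroups under 3 members report NaN), p-value
from the t transform with n − 2 df (reported, never used for selection),
and MSE. Nested selection is the default because selection-on-all-data
leaks the held-out fold into the feature choice; `paper_mode=True` provides
that leakier protocol for comparability, and the null-calibration test
verifies the nested mode shows no optimistic bias where the leaky mode does.

## Reliability and weights

Split halves use 1-based frame parity (odd = positions 1, 3, …), giving
38 + 37 frames from 75; the choice of which half is "odd" only relabels
them. Both halves support the 5-level decomposition (2⁵ ≤ 37); a 64-frame
minimum is enforced. Frequency features are fully recomputed on each half
rather than reused from the full segment. Indicator weights aggregate
|standardised coefficients| by sum (sign-robust; a mean option exists);
group SDs in the distances-vs-angles t-test use divisor n − 1 (the pooled
t-test convention).

## Problem sizes and numerical choices

The shipped evaluation surfaces use synthetic cohorts of n = 150 (trait
recovery), n = 30 (reliability, three seeds per keypoint-noise level 0/5/15
px) and n = 200 with 40 trait permutations (null calibration) — sizes at
which the measured quantities are stable across seeds while the full suite
remains quick to run. Degenerate inputs are handled explicitly: zero-length
bone vectors raise, constant series map higher moments to 0, constant
prediction vectors report NaN correlations, and candidate features collinear
with the selected design contribute nothing (coefficient 0) in the
selection scan.

## Known limitations

- Under permuted (null) traits the pooled CV correlation is centred at zero
  but somewhat wider than the 1/√n independence width, because the greedy
  selector still picks its budget of spurious features inside each training
  fold; the null-calibration surface checks the centring and the absence of
  optimistic bias, not a parametric null width.
- The facing heuristic assumes a monotone apparent-size trend while
  approaching; pacing in place or circular paths need explicit labels.
- Only `people[0]` of a multi-person frame is used (single-walker protocol).
- Indicator weights are defined for the linear model only; coefficients of
  correlated selected features are not variance-decomposed, so weights are
  attribution by magnitude, not unique variance explained.
- Real-cohort effect sizes are out of reach of the synthetic surfaces by
  construction; the simulator calibrates the machinery, not the phenomenon.
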