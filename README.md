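# gaittrait

Psychological trait prediction from ordinary 2D video gait. `gaittrait`
turns OpenPose BODY25 keypoint streams (25 joints × (x, y, confidence) at
25 Hz) into a 2,472-dimensional gait feature vector and trains regression
models that predict a self-report trait score (e.g. a Rosenberg self-esteem
total), with the full evaluation protocol: pooled 10-fold cross-validated
Pearson correlation and MSE, odd–even split-half reliability of the model
predictions, and indicator-level weight analysis. A synthetic articulated
walker with a planted linear trait makes the entire pipeline testable and
reproducible without human recordings.

It is aimed at researchers in behavioural phenotyping who have per-frame
2D pose output (or want to prototype against simulated walkers) and need a
transparent, auditable path from keypoints to a validated trait model.

## Method

1. **Preprocessing.** Face-toward (approaching-camera) intervals are
   selected — pose estimation is more accurate there — using either
   metadata labels or an apparent-torso-size trend heuristic. Every joint is
   re-referenced to the MidHip (joint 8), which is then dropped, leaving 24
   joints / 48 channels. Each channel is smoothed with the binomial low-pass
   kernel c = [1, 4, 6, 4, 1]/16, Out[i] = Σⱼ c[j]·In[i+j], and the segment
   is centre-cropped to 75 frames (3 s at 25 Hz, ≥ 4 gait cycles expected).
2. **Time-domain features (1,320).** Ten statistics (max, min, mean, median,
   population variance, RMS, moment skewness, excess kurtosis, absolute
   energy Σx², coefficient of variation) over four series families: the 48
   raw channels, their first differences Δf_k = f_{k+1} − f_k, 26 per-axis
   inter-joint distance channels (13 pairs × {|Δx|, |Δy|}), and 10
   inter-joint angle series (arccos of the clamped cosine at the vertex
   joint): 48·10 + 48·10 + 26·10 + 10·10 = 1,320.
3. **Frequency-domain features (1,152).** A 5-level orthonormal Haar DWT per
   channel, X = D1 + D2 + D3 + D4 + D5 + A5, with |max|, mean, population
   variance and energy per band: 48·6·4 = 1,152.
4. **Modeling.** Z-scored features, greedy sequential forward selection
   maximising the pooled out-of-fold CV Pearson r, and seven regressors
   (Gaussian process, linear regression, random forest, and linear / poly /
   RBF / sigmoid SVR). Selection is nested inside each evaluation fold by
   default; a `paper_mode` runs it once on all data for comparability.
5. **Reliability & weights.** Each 75-frame segment is split into its odd
   (38) and even (37) frame halves, features are recomputed per half, both
   halves are scored with the unmodified full model, and r_split is the
   Pearson correlation of the two prediction vectors. For linear models,
   |standardised coefficients| aggregate to indicator level (A0–A9, D1–D13,
   raw/diff/wavelet), and a pooled two-sample t-test (df = 13 + 10 − 2 = 21)
   contrasts distance against angle indicators.

## Worked example

```python
import gaittrait as gt

cohort = gt.simulate_cohort(gt.CohortConfig(n_walkers=150, seed=11))
X = gt.extract_cohort_features(cohort.sequences)   # 150 x 2472 DataFrame
y = cohort.traits["score"].to_numpy()              # mean 31.40, SD 4.55

report = gt.cross_validate(X, y, algorithm="lr", k=10, seed=0,
                           subgroup_labels=cohort.traits["sex"])
print(f"r = {report.r_all:.2f}, mse = {report.mse:.2f}")
```

prints

```
r = 0.85, mse = 5.72
```

i.e. pooled out-of-fold predictions correlate 0.85 with the planted trait
(whose oracle ceiling under the default trait-noise level is ≈ 0.88), with a
mean squared error of 5.7 score points² against a trait variance of 20.7.
The same cohort with `trait_noise_sd=0` reaches r ≈ 1.0, and permuting the
scores drives r to ≈ 0 — the two calibration anchors of the protocol.

The same pipeline is available from the shell:

```bash
gaittrait simulate -n 10 --seed 3 --out cohort/
gaittrait extract cohort/ --out features.csv
gaittrait train features.csv cohort/traits.csv --out model.joblib
gaittrait evaluate features.csv cohort/traits.csv --subgroup sex --out report.json
gaittrait reliability cohort/ model.joblib --out reliability.json
```

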