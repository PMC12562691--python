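# Methods

## Pipeline and assumptions

The package classifies seizure *types* from ictal EEG, not seizure vs.
non-seizure. The unit of analysis is the 1 s segment: each labeled
recording is resampled to 250 Hz, bandpassed 0.5–100 Hz, decomposed into
the five clinical bands, and sliced into 1 s windows stepped by 0.5 s.
Every segment inherits its recording's seizure-type label; folds stratify
by label at the segment level, so segments of one seizure may appear in
different folds. This mirrors the segment-wise protocol the pipeline
implements, and it is optimistic relative to patient- or seizure-level
validation — `run_cv` therefore also records per-recording group ids so a
grouped split can be layered on by the caller.

### Filtering

All filters are zero-phase linear-phase FIR (windowed-sinc, Hamming),
delegated to `mne.filter.filter_data` with its default transition
bandwidths `min(max(0.25·f_edge, 2 Hz), f_edge)` (low edge) and
`min(max(0.25·f_edge, 2 Hz), nyquist − f_edge)` (high edge). Two practical
consequences are documented by tests: a tone at 3 Hz — one transition
half-width below the 4 Hz theta edge — is attenuated only ~6 dB by the
theta filter, and the inter-band gaps (7–8, 12–13 Hz) are kept exactly as
defined, with no re-tiling. Band filtering is applied to the continuous
record *before* segmentation so windows carry no per-slice edge
transients.

### Features (13 per band, 65 per segment)

All moments are population (1/N) moments; kurtosis is excess kurtosis
(the −3 convention) but keeps the name `kurtosis`. Sample entropy follows
the Richman–Moorman conventions: Chebyshev distance, self-matches
excluded, tolerance r = 0.2·SD of the very band-filtered window being
scored, m = 2; when no (m+1)-length match exists the estimate is capped
at ln((N−m)(N−m−1)) − ln 2. Wavelet energies come from a 4-level db4
decomposition; the index mapping is a package convention: E0 = level-4
approximation, E1…E4 = details from coarsest to finest. The default
boundary mode is symmetric padding (the wavelet library's default);
periodization is used where energy conservation is asserted, and the mode
is a config key. The Hurst exponent uses block-averaged R/S over
non-overlapping blocks of size τ = 2…20 with a least-squares log–log
slope, no small-sample correction, clipped to [0, 1.5]. Hjorth mobility
and complexity use population variances of first/second differences.

Degenerate (constant) windows map to fixed values — moments (μ, 0, 0, 0),
SampEn 0, Hurst 0.5, Hjorth (0, 0) — so the feature matrix is NaN-free by
construction, which the MI estimator and the classifiers require.

Multichannel recordings yield one 65-vector per segment by computing
features per channel and averaging (configurable: median or a single
channel). This keeps the dimensionality independent of the montage.

### Mutual-information selection

The estimator is the k-nearest-neighbour method for continuous features
against discrete labels: per sample, the distance to its k-th neighbour
within the same class defines a radius; the count mᵢ of samples of any
class strictly inside that radius enters
I = ψ(N) + ψ(k) − ⟨ψ(N_y)⟩ − ⟨ψ(mᵢ)⟩, clipped at 0, reported in nats,
k = 3 by default. Ties are broken by a seeded jitter with SD
1e-10 · max(1, mean |x|); the max(1, ·) guard matters because standardized
columns have mean ≈ 0 and a mean-proportional jitter would vanish exactly
where ties are most common. The jitter seed is derived from the column's
content, so duplicated columns always score identically and appending
columns never perturbs existing scores. Selection keeps the top k = 30 by
score, ties broken by ascending name.

By default scoring and selection run inside each training fold
(leakage-safe); `cv_mode="paper_compat"` reproduces the
once-per-dataset usage (global standardization + selection before CV).
The 5 × 13 MI heatmap is always produced from a global, descriptive
scoring pass — it is a visualization, not part of the fitted pipeline.

### Classifiers and imbalance handling

Classifier internals come from scikit-learn (SVM-RBF with balanced class
weights and probability estimates enabled, KNN k = 5, decision tree and
random forest with balanced weights), LightGBM (balanced weights),
CatBoost (auto-balanced weights; skipped with a named notice when the
library is absent) and XGBoost (`multi:softprob` with
inverse-class-frequency sample weights n/(K·n_c)). Only the listed
settings deviate from library defaults. SMOTE (for KNN) is implemented in
the package from its defining rule — synthetic minority rows
xᵢ + u·(x_nn − xᵢ), u ∈ [0, 1), x_nn among the k = 5 same-class nearest
neighbours, every class raised to the majority count — and is applied to
training rows only. The null model draws a flat-Dirichlet probability
vector per test segment from a seeded generator; its argmax feeds the
label metrics.

### Metrics

Implemented from first principles and cross-checked against library
oracles in tests: accuracy = trace/total; one-vs-rest per-class
precision/recall/F1 with support weighting and the zero-division
convention P = 0 when a class receives no predictions; AUC per class via
the Mann–Whitney rank statistic with midranks (identical to trapezoidal
ROC integration), support-weighted over classes present in the truth.
Class order is fixed alphabetical: ABSZ, CPSZ, FNSZ, GNSZ, TCSZ, TNSZ.

## Synthetic generator

Each seizure type is a `SeizureTypeProfile`: five relative band-power
weights, an optional spike-wave fundamental, a γ-burst rate, an RMS
amplitude and a white-noise SD. A recording is a sum of unit-RMS
band-limited Gaussian noise components (rFFT masking) scaled by
√weight·amplitude, plus an optional harmonic-sharpened spike-wave train
(the ABSZ stand-in uses the classic 3 Hz fundamental), plus
Gaussian-windowed 40–70 Hz tones at Poisson times, plus white noise.
Channels mix a shared and an independent draw (weight 0.5 each) so
channel averaging is exercised. Per-recording seeds are `seed + index`.

Default profile parameters (amplitudes 50–95 µV, noise 4–8 µV, distinct
band-power vectors, γ-dominant TNSZ, δ/θ-dominant ABSZ) were chosen once
as plausible desk-scale stand-ins. They are **not** clinically validated
templates: the generator reproduces band-power contrasts, periodic
transients and bursts, but none of the non-stationarity, artifacts,
inter-patient variability or montage effects of clinical EEG. Passing
tests therefore demonstrate that the pipeline's mechanics recover class
structure that is genuinely present in the signal — on this generator the
classes are nearly separable (boosted-tree accuracy ≈ 0.99) — and say
nothing about attainable accuracy on clinical corpora.

The emulated study corpus keeps the published imbalance:
100/78/100/47/100/47 recordings for FNSZ/ABSZ/CPSZ/TCSZ/GNSZ/TNSZ
(472 total), durations 14.66 s and up. Test fixtures and the acceptance
script scale the class counts down proportionally (and cap durations at
tens of seconds) to keep runs at desk scale; the scaled sizes are stated
where used (≈ 3.8 k segments for the recovery checks, ≥ 10 k segments for
the null-model calibration).

## Numerical and I/O conventions

- Windows/steps convert to samples by rounding (1 s/0.5 s at 250 Hz →
  250/125 exactly); trailing partial windows are dropped.
- Resampling is polyphase with anti-aliasing; the output length is
  `round(n·target/fs)`, trimmed or edge-padded after the filter.
- EDF files are written by a minimal built-in 16-bit writer (one data
  record spanning the recording, per-channel physical range fitted and
  rounded outward to header precision) and read back through `mne`.
  16-bit quantization bounds the round-trip error at one LSB of the
  physical range (~1.5e-5 of the range); `.npy` and delimited-text round
  trips are exact.
- z-scoring flags columns with fitted SD < 1e-12 and maps them to 0.
- All randomness flows through explicit integer seeds; corpora, SMOTE,
  fold plans, MI jitter and null-model draws are bit-reproducible.

## Known limitations

- No artifact rejection beyond the broadband filter (no notch, ICA or
  EMG/eye-blink handling) and no artifact simulation in the generator.
- Segment-level CV is optimistic when segments of one seizure span folds;
  grouped CV by recording is exposed but not the default.
- The MI estimator inherits the known small-sample bias of
  nearest-neighbour estimators on heavily tied data; tests bound its
  deviation from the exact plug-in at 0.05 nats on coarse-valued inputs.
- CatBoost support requires an optional dependency; without it the model
  is reported as unavailable and runs continue.
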