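# ictalfeat

Segment-wise, multi-band EEG feature engineering and mutual-information-ranked
classification of seizure types.

## The problem

Epileptic seizures come in distinct types — focal non-specific (FNSZ), absence
(ABSZ), complex partial (CPSZ), tonic-clonic (TCSZ), generalized non-specific
(GNSZ) and tonic (TNSZ) — whose discrimination from scalp EEG matters for
treatment choice but is tedious and subjective when done by eye. `ictalfeat`
implements an automated pipeline for multi-class seizure-type classification
aimed at researchers working with ictal EEG: it turns labeled multichannel
recordings into interpretable per-band features, ranks those features by how
much information they carry about the seizure type, and benchmarks standard
classifiers under imbalance-aware stratified cross-validation.

Because clinical seizure corpora are access-restricted, the package ships a
synthetic ictal-EEG generator with one spectral profile per seizure type, so
the entire pipeline is testable and reproducible end to end without any
protected data.

## The method

1. **Preprocessing** — resample to 250 Hz, zero-phase FIR bandpass 0.5–100 Hz,
   decompose into the five clinical bands δ (1–4 Hz), θ (4–7), α (8–12),
   β (13–30), γ (30–80), then slice into 1 s windows with a 0.5 s step.
2. **Features** — per window and band, 13 descriptors averaged over channels:
   population mean, variance, skewness, excess kurtosis; sample entropy
   SampEn(m = 2, r = 0.2·σ); five wavelet energies Eⱼ = Σₖ c²ⱼ,ₖ from a 4-level
   db4 decomposition; the rescaled-range Hurst exponent
   H = slope of log ⟨R/S⟩(τ) vs log τ, τ = 2…20; and Hjorth mobility
   √(Var Δx / Var x) and complexity. Band-major ordering gives a
   65-dimensional vector per segment, z-scored before use.
3. **Selection** — mutual information I(X; Y) between each feature and the
   label, estimated with a k-nearest-neighbour estimator for continuous X vs
   discrete Y (ψ(N) + ψ(k) − ⟨ψ(N_y)⟩ − ⟨ψ(mᵢ)⟩, in nats); the top k = 30
   features are retained.
4. **Classification** — SVM, KNN, decision tree, random forest, LightGBM,
   CatBoost (when installed) and XGBoost under 10-fold stratified CV, each
   with its imbalance strategy (balanced class weights; SMOTE for KNN;
   inverse-class-frequency sample weights for XGBoost), plus a feature-free
   null model. Standardization and selection are fitted inside each training
   fold by default.
5. **Evaluation** — accuracy, support-weighted precision/recall/F1 and
   weighted one-vs-rest AUC, implemented from first principles, with pooled
   confusion matrices and a 5 × 13 band-by-feature MI heatmap.

## Worked example

```bash
python examples/crossvalidate.py
```

builds a 38-recording synthetic corpus (~1000 segments), extracts the
65-column feature matrix and runs 5-fold CV:

```
XGBoost  accuracy 0.9899 ± 0.0074   AUC 0.9994 ± 0.0007
Null     accuracy 0.1872 ± 0.0232   AUC 0.5109 ± 0.0298
```

The boosted model recovers the class structure the generator encodes almost
perfectly, while the null model sits at chance for six classes (accuracy
≈ 1/6, one-vs-rest AUC ≈ 0.5). `examples/rank_features.py` prints the MI
ranking — γ-band variance and wavelet energies lead, matching the
high-frequency structure that separates the synthetic seizure types — and
`examples/simulate_and_extract.py` walks through simulation and feature
extraction alone.

The same stages are available as a CLI for shell use:

```bash
ictalfeat simulate --out corpus/ --fmt edf
ictalfeat extract  --manifest corpus/manifest.tsv --out features.tsv
ictalfeat select   --features features.tsv --k 30 --out selection.json
ictalfeat evaluate --features features.tsv --models xgboost,null --out report/
ictalfeat run      --out report/          # end-to-end with defaults
```

## Layout

```
src/ictalfeat/    synth, io, preprocess, features, mi, classify, evaluate,
                  report, cli
examples/         narrative scripts, one per capability
tests/            pytest suite incl. brute-force oracles for SampEn, R/S
                  Hurst and plug-in MI
docs/methods.md   model, conventions, parameter defaults, limitations
```
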