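"""Cross-validate classifiers on a synthetic corpus, with the null baseline.

Runs 5-fold stratified CV (10 folds need a larger corpus) with fold-wise
standardization and MI selection, comparing a gradient-boosted model
against the feature-free null model that guesses uniformly at random.
"""

import ictalfeat as icf
from ictalfeat.classify import ModelSpec

recordings = icf.simulate_corpus(
    icf.default_profiles(),
    counts_per_class={"FNSZ": 8, "CPSZ": 8, "GNSZ": 8,
                      "ABSZ": 6, "TCSZ": 4, "TNSZ": 4},
    duration_range_s=(10.0, 15.0), seed=2)
fm = icf.extract_corpus(recordings, icf.RunConfig(seed=2))

plan = icf.make_fold_plan(fm.labels, n_folds=5, seed=2)
specs = [ModelSpec("XGBoost", "inverse_freq_sample_weight", seed=2),
         ModelSpec("Null", "none", seed=2)]
report = icf.run_cv(fm, specs, plan, selection_k=30)

for name, res in report.results.items():
    print(f"{name:8s} accuracy {res.mean['accuracy']:.4f} ± {res.sd['accuracy']:.4f}   "
          f"AUC {res.mean['auc']:.4f} ± {res.sd['auc']:.4f}")
# The boosted model should recover the class structure the generator
# encodes (accuracy near 1); the null model sits at chance: accuracy near
# 1/6 and one-vs-rest AUC near 0.5.
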