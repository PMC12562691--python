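"""Rank the 65 features by mutual information with the seizure-type label.

Extracts features from a modest synthetic corpus, z-scores them, scores
every column with the k-nearest-neighbour MI estimator and prints the
top 10.  On the synthetic profiles the gamma-band energy features
dominate, mirroring the band structure the generator encodes.
"""

import ictalfeat as icf

recordings = icf.simulate_corpus(
    icf.default_profiles(),
    counts_per_class={"FNSZ": 6, "CPSZ": 6, "GNSZ": 6,
                      "ABSZ": 4, "TCSZ": 3, "TNSZ": 3},
    duration_range_s=(10.0, 15.0), seed=1)
fm = icf.extract_corpus(recordings, icf.RunConfig(seed=1))

std, *_ = icf.standardize(fm)
scores = icf.score_all(std, k_neighbors=3, seed=1)
selection = icf.select_top_k(scores, k=30)

print(f"scored {len(scores)} features on {fm.n_segments} segments; "
      f"kept top {len(selection.selected_names)}")
for name in selection.selected_names[:10]:
    print(f"  {name:28s} {scores[name]:.3f} nats")
# Higher MI = the feature's distribution differs more across seizure
# types; 0 nats would mean the feature is uninformative about the label.
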