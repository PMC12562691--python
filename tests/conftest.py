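import numpy as np
import pytest

import ictalfeat as icf

# Imbalanced desk-scale corpus: paper-ratio class counts scaled down, short
# durations; yields > 3000 one-second segments.
CORPUS_COUNTS = {"FNSZ": 25, "CPSZ": 25, "GNSZ": 25,
                 "ABSZ": 19, "TCSZ": 12, "TNSZ": 12}
CORPUS_SEED = 11


@pytest.fixture(scope="session")
def corpus_features() -> icf.FeatureMatrix:
    """Feature matrix of the default imbalanced synthetic corpus."""
    recordings = icf.simulate_corpus(
        icf.default_profiles(), CORPUS_COUNTS,
        duration_range_s=(14.66, 20.0), fs=250.0, n_channels=2,
        seed=CORPUS_SEED)
    cfg = icf.RunConfig(seed=CORPUS_SEED)
    fm = icf.extract_corpus(recordings, cfg)
    assert fm.n_segments >= 3000
    return fm


@pytest.fixture(scope="session")
def small_features(corpus_features) -> icf.FeatureMatrix:
    """Deterministic ~600-segment subsample for cheaper structural tests."""
    rng = np.random.default_rng(0)
    idx = np.sort(rng.choice(corpus_features.n_segments, 600, replace=False))
    return icf.FeatureMatrix(
        values=corpus_features.values[idx],
        names=list(corpus_features.names),
        labels=corpus_features.labels[idx],
        group_ids=corpus_features.group_ids[idx],
        start_times=corpus_features.start_times[idx])
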