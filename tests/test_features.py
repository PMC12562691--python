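import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ictalfeat as icf
from ictalfeat.features import FEATURE_ORDER, SampEnConfig, segment_features
from ictalfeat.preprocess import BAND_ORDER, SegmentedBands

from .oracles import hurst_bruteforce, sampen_bruteforce


class TestStatMoments:
    def test_hand_computed_example(self):
        mu, var, skew, kurt = icf.stat_moments(np.array([1.0, 2.0, 3.0, 4.0]))
        assert mu == pytest.approx(2.5)
        assert var == pytest.approx(1.25)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(-1.36)

    def test_constant_convention(self):
        assert icf.stat_moments(np.full(4, 5.0)) == (5.0, 0.0, 0.0, 0.0)

    def test_gaussian_moments_monte_carlo(self):
        x = np.random.default_rng(12345).standard_normal(100_000)
        _, var, skew, kurt = icf.stat_moments(x)
        assert var == pytest.approx(1.0, abs=0.02)
        assert skew == pytest.approx(0.0, abs=0.05)
        assert kurt == pytest.approx(0.0, abs=0.1)

    def test_too_short(self):
        with pytest.raises(ValueError):
            icf.stat_moments(np.array([1.0]))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 100.0))
    def test_scaling_behavior(self, seed, a):
        """a*x scales the mean by a, variance by a^2, and leaves the
        shape moments unchanged."""
        x = np.random.default_rng(seed).standard_normal(64)
        m0 = icf.stat_moments(x)
        m1 = icf.stat_moments(a * x)
        assert m1[0] == pytest.approx(a * m0[0], rel=1e-9, abs=1e-9)
        assert m1[1] == pytest.approx(a**2 * m0[1], rel=1e-9)
        assert m1[2] == pytest.approx(m0[2], rel=1e-6, abs=1e-9)
        assert m1[3] == pytest.approx(m0[3], rel=1e-6, abs=1e-9)


class TestSampleEntropy:
    def test_constant_signal_zero(self):
        assert icf.sample_entropy(np.full(100, 3.0)) == 0.0

    def test_alternating_signal_perfectly_regular(self):
        x = np.tile([1.0, -1.0], 125)
        assert icf.sample_entropy(x) == 0.0

    def test_matches_bruteforce_oracle(self):
        for seed in range(10):
            x = np.random.default_rng(seed).uniform(size=250)
            fast = icf.sample_entropy(x)
            slow = sampen_bruteforce(x)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_positive_scale_invariance(self):
        x = np.random.default_rng(77).standard_normal(250)
        assert icf.sample_entropy(3.7 * x) == pytest.approx(
            icf.sample_entropy(x), abs=1e-12)

    def test_embedding_dimension_config(self):
        x = np.random.default_rng(5).standard_normal(250)
        assert icf.sample_entropy(x, SampEnConfig(m=1)) == pytest.approx(
            sampen_bruteforce(x, m=1), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            icf.sample_entropy(np.array([1.0, 2.0, 3.0]))


class TestWaveletEnergies:
    def test_zero_signal(self):
        np.testing.assert_array_equal(icf.wavelet_energies(np.zeros(128)),
                                      np.zeros(5))

    def test_impulse_energy_conserved_periodized(self):
        x = np.zeros(128)
        x[10] = 1.0
        e = icf.wavelet_energies(x, mode="periodization")
        assert e.sum() == pytest.approx(1.0, abs=1e-10)

    def test_energy_conservation_random_signal(self):
        x = np.random.default_rng(3).standard_normal(256)
        e = icf.wavelet_energies(x, mode="periodization")
        assert e.sum() == pytest.approx(np.sum(x**2), abs=1e-8)

    def test_slow_tone_dominates_approximation(self):
        t = np.arange(250) / 250.0
        e = icf.wavelet_energies(np.sin(2 * np.pi * 2.0 * t))
        assert e[0] == max(e)

    def test_too_short(self):
        with pytest.raises(ValueError):
            icf.wavelet_energies(np.zeros(8))


class TestHurst:
    def test_constant_convention(self):
        assert icf.hurst_rs(np.full(250, 2.0)) == 0.5

    def test_matches_bruteforce_oracle(self):
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(250)
            assert icf.hurst_rs(x) == pytest.approx(
                hurst_bruteforce(x), abs=1e-12)

    def test_persistence_ordering(self):
        """Integrated noise (a random walk) is more persistent than the
        noise itself on at least 18 of 20 seeds."""
        wins = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(250)
            if icf.hurst_rs(np.cumsum(x)) > icf.hurst_rs(x):
                wins += 1
        assert wins >= 18

    def test_result_clipped(self):
        x = np.random.default_rng(1).standard_normal(250)
        assert 0.0 <= icf.hurst_rs(x) <= 1.5

    def test_too_short(self):
        with pytest.raises(ValueError):
            icf.hurst_rs(np.zeros(15))


class TestHjorth:
    def test_constant_convention(self):
        assert icf.hjorth(np.full(10, 1.0)) == (0.0, 0.0)

    def test_sinusoid_closed_form(self):
        t = np.arange(500) / 250.0
        mob, comp = icf.hjorth(np.sin(2 * np.pi * 10.0 * t))
        assert mob == pytest.approx(2 * np.sin(np.pi * 10.0 / 250.0), abs=1e-3)
        assert comp == pytest.approx(1.0, abs=1e-2)

    def test_iid_noise_closed_form(self):
        x = np.random.default_rng(1234).standard_normal(10_000)
        mob, comp = icf.hjorth(x)
        assert mob == pytest.approx(np.sqrt(2), abs=0.05)
        assert comp == pytest.approx(np.sqrt(3) / np.sqrt(2), abs=0.05)

    def test_too_short(self):
        with pytest.raises(ValueError):
            icf.hjorth(np.array([1.0, 2.0]))


def _segment_bands_for(rec: icf.Recording) -> SegmentedBands:
    return icf.segment_bands(icf.decompose_bands(icf.broadband_filter(rec)))


class TestExtract:
    def test_full_matrix_has_65_unique_band_major_names(self):
        rec = icf.simulate_recording(icf.default_profiles()[0], 3.0, 250.0, 2, 0)
        fm = icf.extract_features(_segment_bands_for(rec), label="ABSZ")
        assert len(fm.names) == 65
        assert len(set(fm.names)) == 65
        grid = np.array(fm.names).reshape(5, 13)
        for row, band in zip(grid, BAND_ORDER):
            assert all(name.startswith(band + "_") for name in row)
        assert [n.split("_", 1)[1] for n in grid[0]] == list(FEATURE_ORDER)

    def test_single_band_yields_13_columns(self):
        rec = icf.simulate_recording(icf.default_profiles()[1], 3.0, 250.0, 1, 0)
        bands = icf.decompose_bands(icf.broadband_filter(rec))
        seg = icf.segment_bands({"gamma": bands["gamma"]})
        fm = icf.extract_features(seg, label="CPSZ")
        assert len(fm.names) == 13

    def test_identical_channels_match_single_channel(self):
        rec1 = icf.simulate_recording(icf.default_profiles()[2], 3.0, 250.0, 1, 4)
        rec3 = icf.Recording(np.repeat(rec1.signal, 3, axis=0), fs=250.0,
                             label=rec1.label)
        fm1 = icf.extract_features(_segment_bands_for(rec1))
        fm3 = icf.extract_features(_segment_bands_for(rec3))
        np.testing.assert_allclose(fm3.values, fm1.values, rtol=1e-10)

    def test_values_finite_and_labels_propagate(self, small_features):
        assert np.all(np.isfinite(small_features.values))
        assert set(small_features.labels) <= set(icf.CLASS_ORDER)

    def test_segment_features_order(self):
        x = np.random.default_rng(0).standard_normal(250)
        vec = segment_features(x, SampEnConfig(), icf.HurstConfig(), "symmetric")
        assert vec.shape == (13,)
        assert vec[0] == pytest.approx(x.mean())


class TestStandardize:
    def test_zscore_identity(self, small_features):
        std, means, sds, const = icf.standardize(small_features)
        assert not const.any()
        np.testing.assert_allclose(std.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(std.values.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_flagged(self):
        fm = icf.FeatureMatrix(values=np.column_stack([np.ones(10),
                                                       np.arange(10.0)]),
                               names=["c", "x"], labels=np.zeros(10),
                               group_ids=np.zeros(10))
        std, _, _, const = icf.standardize(fm)
        assert const[0] and not const[1]
        np.testing.assert_array_equal(std.values[:, 0], 0.0)

    def test_heldout_rows_use_training_parameters(self, small_features):
        fit_rows = np.arange(0, 300)
        std, *_ = icf.standardize(small_features, fit_rows=fit_rows)
        held = std.values[300:]
        # held-out rows are generally not centered under training parameters
        assert np.max(np.abs(held.mean(axis=0))) > 1e-3

    def test_empty_fit_set(self, small_features):
        with pytest.raises(ValueError):
            icf.standardize(small_features, fit_rows=np.array([], dtype=int))
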