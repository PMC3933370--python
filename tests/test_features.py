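import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungsound.cycle_segmentation import RespiratoryCycle
from lungsound.features import (
    FEATURE_SETS,
    LacunarityConfig,
    SampEnConfig,
    cycle_sample_entropy,
    excess_kurtosis,
    extract_features,
    lacunarity,
    lacunarity_profile,
    sample_entropy,
    skewness,
)
from lungsound.signal_io import LungSoundSignal

from conftest import lacunarity_oracle, moment_oracle, sample_entropy_oracle


class TestMoments:
    def test_gaussian_excess_kurtosis_is_zero(self):
        x = np.random.default_rng(0).standard_normal(10**6)
        assert abs(excess_kurtosis(x)) <= 0.05

    def test_two_point_symmetric_law(self):
        assert excess_kurtosis([1, -1, 1, -1]) == pytest.approx(-2.0)

    def test_kurtosis_matches_direct_moment_sums(self):
        x = [0.0, 0.0, 0.0, 1.0, 5.0]
        _, _, _, kurt = moment_oracle(x)
        assert excess_kurtosis(x) == pytest.approx(kurt, abs=1e-12)

    def test_symmetric_sequence_has_zero_skewness(self):
        assert skewness([-2, -1, 0, 1, 2]) == pytest.approx(0.0, abs=1e-15)

    def test_skewness_matches_direct_moment_sums(self):
        assert skewness([0, 0, 0, 1]) == pytest.approx(2 / np.sqrt(3))
        x = [0.3, -1.2, 4.0, 0.0, 2.2, -0.7]
        assert skewness(x) == pytest.approx(moment_oracle(x)[2], abs=1e-12)

    def test_skewness_sign_flip_antisymmetry(self, rng):
        x = rng.normal(size=200)
        assert skewness(-x) == pytest.approx(-skewness(x), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            excess_kurtosis(np.ones(10))
        with pytest.raises(ValueError):
            skewness(np.ones(10))


class TestLacunarity:
    def test_constant_series_gives_one(self):
        for l in (1, 2, 5):
            assert lacunarity(np.full(20, 3.0), l) == pytest.approx(1.0)

    def test_worked_example_1234(self):
        # boxes of length 2: masses (3, 5, 7); M1=5, M2=83/3; zeta=83/75
        assert lacunarity([1, 2, 3, 4], 2) == pytest.approx(83 / 75)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            l = int(rng.integers(1, n))
            got = lacunarity(x, l)
            want = lacunarity_oracle(list(x), l)
            assert got == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=4, max_size=40),
        st.integers(1, 3),
    )
    def test_never_below_one(self, xs, l):
        x = np.asarray(xs)
        if l >= x.size or np.sum(np.abs(x)) == 0:
            return
        assert lacunarity(x, l) >= 1.0 - 1e-12

    def test_all_zero_mass_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            lacunarity(np.zeros(10), 2)

    def test_profile_summary_reduces_and_bounds(self, rng):
        x = rng.normal(size=64)
        single = lacunarity_profile(x, LacunarityConfig(box_lengths=(4,)))
        assert single.summary == pytest.approx(lacunarity(x, 4))
        prof = lacunarity_profile(x)
        assert min(prof.values) <= prof.summary <= max(prof.values)
        const = lacunarity_profile(np.full(64, 2.0))
        assert const.summary == pytest.approx(1.0)


class TestSampleEntropy:
    def test_constant_with_absolute_tolerance_is_zero(self):
        cfg = SampEnConfig(m=2, r=0.1, r_is_absolute=True)
        assert sample_entropy(np.ones(30), cfg) == pytest.approx(0.0)

    def test_constant_with_relative_tolerance_errors(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            sample_entropy(np.ones(30))

    def test_alternating_sequence_is_perfectly_predictable(self):
        x = np.tile([1.0, 2.0], 30)
        cfg = SampEnConfig(m=2, r=0.5, r_is_absolute=True)
        assert sample_entropy(x, cfg) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 3, 5, 7])
    def test_matches_double_loop_oracle(self, seed):
        x = np.random.default_rng(seed).random(50)
        r_abs = 0.2 * x.std()
        want = sample_entropy_oracle(list(x), 2, r_abs)
        assert sample_entropy(x) == pytest.approx(want, abs=1e-12)

    def test_no_matches_errors_with_counts(self):
        x = np.array([0.0, 100.0, -50.0, 1000.0, -800.0, 5.0])
        with pytest.raises(ValueError, match="no matches"):
            sample_entropy(x, SampEnConfig(m=2, r=1e-6, r_is_absolute=True))

    def test_windowed_cycle_entropy_matches_plain_when_short(self, rng):
        x = rng.normal(size=800)
        assert cycle_sample_entropy(x) == pytest.approx(sample_entropy(x))


class TestScaleInvariance:
    def test_all_features_invariant_to_amplitude_scaling(self, rng):
        x = rng.normal(size=400)
        a = 7.3
        assert excess_kurtosis(a * x) == pytest.approx(excess_kurtosis(x), abs=1e-9)
        assert skewness(a * x) == pytest.approx(skewness(x), abs=1e-9)
        assert lacunarity(a * x, 8) == pytest.approx(lacunarity(x, 8), abs=1e-9)
        assert sample_entropy(a * x) == pytest.approx(sample_entropy(x), abs=1e-9)


class TestExtractFeatures:
    def _cycles(self, n, length, rate=8000.0):
        return [
            RespiratoryCycle(
                start_sample=i * length,
                end_sample=(i + 1) * length,
                transition_points=(i * length + length // 2,),
                sampling_rate_hz=rate,
            )
            for i in range(n)
        ]

    def test_set_dimensionality(self, rng):
        sig = LungSoundSignal(rng.normal(size=8000) / 10, 8000.0, "normal")
        cycles = self._cycles(2, 4000)
        for fs, fields in FEATURE_SETS.items():
            feats = extract_features(sig, cycles, feature_set=fs)
            assert len(feats) == 2
            for f in feats:
                assert f.values().shape == (len(fields),)
                assert np.all(np.isfinite(f.values()))
        set1 = extract_features(sig, cycles, feature_set="set1")[0]
        assert set1.lacunarity_zeta is None and set1.sample_entropy_alpha is None

    def test_stationary_noise_gives_similar_features_across_cycles(self, rng):
        sig = LungSoundSignal(rng.normal(size=16000) / 10, 8000.0)
        f1, f2 = extract_features(sig, self._cycles(2, 8000), feature_set="set3")
        assert f1.lacunarity_zeta == pytest.approx(f2.lacunarity_zeta, rel=0.1)
        assert f1.sample_entropy_alpha == pytest.approx(
            f2.sample_entropy_alpha, rel=0.1
        )

    def test_degenerate_cycle_skipped_not_fatal(self, rng, caplog):
        import logging

        x = np.concatenate([np.zeros(4000), rng.normal(size=4000) / 10])
        sig = LungSoundSignal(x, 8000.0)
        with caplog.at_level(logging.WARNING, logger="lungsound.features"):
            feats = extract_features(sig, self._cycles(2, 4000), feature_set="set1")
        assert len(feats) == 1
        assert any("skipping cycle" in r.message for r in caplog.records)

    def test_cycle_past_signal_end_errors(self, rng):
        sig = LungSoundSignal(rng.normal(size=1000) / 10, 8000.0)
        with pytest.raises(ValueError, match="past the end"):
            extract_features(sig, self._cycles(1, 2000), feature_set="set1")
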