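"""Fuzzy entropy and multiscale profiles against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mferobust import (EntropyParams, amplitude_transform, coarse_grain,
                       compute_at_bounds, fuzzy_entropy, mfe_profile,
                       scale_average, subject_channel_profiles)
from mferobust.entropy import RMode, default_combinations, multi_combination_profiles
from mferobust.preprocess import AmplitudeState
from tests.conftest import fuzzy_entropy_bruteforce, make_epochs


class TestCoarseGrain:
    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_pairwise_means(self):
        assert np.array_equal(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_length_is_floor(self):
        assert len(coarse_grain(np.arange(600.0), 20)) == 30
        assert len(coarse_grain(np.arange(10.0), 3)) == 3

    def test_scale_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(5.0), 6)


class TestFuzzyEntropy:
    def test_constant_sequence_is_zero(self):
        assert fuzzy_entropy(np.full(30, 3.7), 2, 2, 0.5) == 0.0

    def test_shift_invariance(self, rng):
        x = rng.integers(-5, 6, size=40).astype(float)
        assert np.isclose(fuzzy_entropy(x + 17.0, 2, 2, 0.4),
                          fuzzy_entropy(x, 2, 2, 0.4), rtol=0, atol=1e-12)
        y = rng.standard_normal(40)
        assert np.isclose(fuzzy_entropy(y + 0.3718, 2, 2, 0.4),
                          fuzzy_entropy(y, 2, 2, 0.4), rtol=0, atol=1e-10)

    def test_joint_scaling_invariance_exact(self, rng):
        """FE(c*x, c**n * r_abs) == FE(x, r_abs), bit-exact for c = 2."""
        x = rng.standard_normal(60)
        for n in (1.0, 2.0):
            assert fuzzy_entropy(2.0 * x, 3, n, 0.25 * 2.0 ** n) == \
                fuzzy_entropy(x, 3, n, 0.25)

    def test_amplitude_sensitivity_without_tolerance_rescaling(self, rng):
        """With fixed r_abs, rescaling the signal changes FE (the bias AT fixes)."""
        x = rng.standard_normal(80)
        r_abs = 0.2 * x.std()
        assert not np.isclose(fuzzy_entropy(3.0 * x, 2, 2, 3.0 * r_abs),
                              fuzzy_entropy(x, 2, 2, r_abs))

    def test_matches_bruteforce_on_reference_sequence(self):
        x = np.array([1, 2, 3, 2, 1, 2, 3, 2, 1, 2], dtype=float)
        got = fuzzy_entropy(x, 2, 2, 0.5)
        expected = fuzzy_entropy_bruteforce(x, 2, 2, 0.5)
        assert abs(got - expected) < 1e-10

    @pytest.mark.parametrize("m,r", default_combinations())
    def test_matches_bruteforce_random_sequences(self, m, r, rng):
        for _ in range(5):
            x = rng.standard_normal(35)
            r_abs = r * x.std()
            got = fuzzy_entropy(x, m, 2, r_abs)
            assert abs(got - fuzzy_entropy_bruteforce(x, m, 2, r_abs)) < 1e-10

    def test_infinite_tolerance_limit(self, rng):
        x = rng.standard_normal(50)
        assert abs(fuzzy_entropy(x, 2, 2, 1e12)) < 1e-6

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            fuzzy_entropy(np.array([1.0, np.nan, 2.0, 3.0, 4.0]), 2, 2, 0.5)
        with pytest.raises(ValueError):
            fuzzy_entropy(rng.standard_normal(4), 3, 2, 0.5)
        with pytest.raises(ValueError):
            fuzzy_entropy(rng.standard_normal(30), 2, 2, 0.0)


class TestMfeProfile:
    def test_single_scale_equals_fuzzy_entropy(self, rng):
        x = rng.standard_normal(120)
        p = EntropyParams(m=2, r_coeff=0.2, scales=(1,))
        prof = mfe_profile(x, p, 0.3)
        assert np.isclose(prof[0], fuzzy_entropy(x, 2, 2, 0.3), atol=1e-12)

    def test_white_noise_entropy_decreases_with_scale(self, rng):
        """Coarse-graining averages out uncorrelated noise -> FE drops."""
        p = EntropyParams(m=2, r_coeff=0.2, scales=tuple(range(1, 21)))
        profiles = []
        for _ in range(20):
            x = rng.standard_normal(600)
            profiles.append(mfe_profile(x, p, 0.2 * x.std()))
        mean_prof = np.mean(profiles, axis=0)
        assert mean_prof[0] > mean_prof[9] > mean_prof[19]

    def test_insufficient_length_names_scale(self):
        p = EntropyParams(m=4, scales=(1, 30))
        with pytest.raises(ValueError, match="scale 30"):
            mfe_profile(np.random.default_rng(0).standard_normal(100), p, 0.3)

    def test_min_length_at_deepest_scale_processed(self, rng):
        # 600 samples at scale 20 -> 30 samples, enough for m up to 4
        x = rng.standard_normal(600)
        p = EntropyParams(m=4, scales=(20,))
        assert np.isfinite(mfe_profile(x, p, 0.4)[0])


class TestScaleAverage:
    def test_constant_profile(self):
        assert scale_average(np.full(20, 1.3)) == pytest.approx(1.3)

    def test_two_point_profile(self):
        assert scale_average(np.array([0.0, 1.0])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scale_average(np.array([]))


class TestSubjectProfiles:
    def test_grid_shape_and_epoch_averaging(self, rng):
        ep = make_epochs(rng.standard_normal((3, 4, 200)))
        p = EntropyParams(m=2, r_coeff=0.2, scales=(1, 2, 5))
        grid = subject_channel_profiles(ep, p)
        assert grid.shape == (3, 3)
        assert np.all(np.isfinite(grid))

    def test_matches_explicit_epoch_mean(self, rng):
        """The grid equals the hand-assembled mean of per-epoch profiles."""
        ep = make_epochs(rng.standard_normal((2, 3, 150)))
        p = EntropyParams(m=2, r_coeff=0.25, scales=(1, 3),
                          r_mode=RMode.PER_SUBJECT_GLOBAL)
        r_abs = 0.25 * ep.epochs.std()
        expected = np.mean(
            [[mfe_profile(ep.epochs[c, e], p, r_abs) for e in range(3)]
             for c in range(2)], axis=1)
        got = subject_channel_profiles(ep, p)
        assert np.allclose(got, expected, atol=1e-10)

    def test_per_epoch_channel_mode_uses_local_sd(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 150)))
        p = EntropyParams(m=2, r_coeff=0.2, scales=(1,),
                          r_mode=RMode.PER_EPOCH_CHANNEL)
        got = subject_channel_profiles(ep, p)
        expected = np.mean([
            fuzzy_entropy(ep.epochs[0, e], 2, 2, 0.2 * ep.epochs[0, e].std())
            for e in range(2)])
        assert np.isclose(got[0, 0], expected, atol=1e-10)

    def test_global_mode_channel_scaling_bias(self, rng):
        """Scaling one channel (shared r reference) changes that channel's FE."""
        epochs = rng.standard_normal((2, 3, 200))
        base = subject_channel_profiles(
            make_epochs(epochs), EntropyParams(m=2, scales=(1,)))
        scaled = epochs.copy()
        scaled[1] *= 4.0
        bumped = subject_channel_profiles(
            make_epochs(scaled), EntropyParams(m=2, scales=(1,)))
        assert not np.isclose(bumped[1, 0], base[1, 0], rtol=1e-3)

    def test_at_then_entropy_is_gain_invariant(self, rng):
        """AT absorbs a subject-level gain exactly, so FE grids match."""
        epochs = rng.standard_normal((2, 4, 120))
        p = EntropyParams(m=2, scales=(1, 2))

        def at_profiles(arr):
            ep = make_epochs(arr)
            at = amplitude_transform(ep, compute_at_bounds(ep))
            return subject_channel_profiles(at, p)

        assert np.array_equal(at_profiles(epochs), at_profiles(2.0 * epochs))

    def test_zero_sd_reference_rejected(self):
        ep = make_epochs(np.zeros((1, 2, 100)))
        with pytest.raises(ValueError, match="zero standard deviation"):
            subject_channel_profiles(ep, EntropyParams(m=2, scales=(1,)))


class TestMultiCombination:
    def test_matches_single_combination_path(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 150)))
        combos = default_combinations()
        multi = multi_combination_profiles(ep, combos, 2.0, (1, 2))
        for ci, (m, r) in enumerate(combos):
            single = subject_channel_profiles(
                ep, EntropyParams(m=m, r_coeff=r, scales=(1, 2)))
            assert np.allclose(multi[ci], single, atol=1e-12)

    def test_nonnegative_on_pipeline_inputs(self, rng):
        ep = make_epochs(rng.standard_normal((2, 3, 300)))
        vals = multi_combination_profiles(ep, None, 2.0, tuple(range(1, 11)))
        assert np.all(vals >= 0)
        assert np.all(np.isfinite(vals))


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_fe_nonnegative_property(seed):
    """FE stays non-negative across random draws (template-nesting heuristic)."""
    x = np.random.default_rng(seed).standard_normal(80)
    assert fuzzy_entropy(x, 2, 2, 0.2 * x.std()) >= 0
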