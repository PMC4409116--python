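"""Unit and property tests for sifting, EMD and the ensemble variant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ermkit import EEMDConfig, SignalIsTrend, eemd, emd, envelope_mean, find_extrema, sift
from ermkit.hht import central_slice

from conftest import two_tone


def brute_force_extrema(x):
    """Independent neighbour-scan oracle (strict extrema, no plateaus)."""
    maxima = [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]
    minima = [i for i in range(1, len(x) - 1) if x[i - 1] > x[i] < x[i + 1]]
    return maxima, minima


class TestFindExtrema:
    def test_single_period_sine(self):
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * t)
        maxima, minima = find_extrema(x)
        assert list(maxima) == [25]
        assert list(minima) == [75]

    @pytest.mark.parametrize("x", [np.arange(50.0), np.zeros(50)])
    def test_monotone_and_constant_have_none(self, x):
        maxima, minima = find_extrema(x)
        assert len(maxima) == 0 and len(minima) == 0

    def test_matches_brute_force_on_random_signals(self, rng):
        for _ in range(20):
            x = rng.standard_normal(200)
            maxima, minima = find_extrema(x)
            bm, bn = brute_force_extrema(x)
            assert list(maxima) == bm and list(minima) == bn

    def test_plateau_contributes_first_sample(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0, -1.0, -1.0, 0.0])
        maxima, minima = find_extrema(x)
        assert list(maxima) == [2]
        assert list(minima) == [7]


class TestEnvelopeMean:
    def test_pure_tone_mean_envelope_near_zero(self):
        t = np.arange(1000) / 100.0  # 10 cycles
        x = np.sin(2 * np.pi * t)
        m = envelope_mean(x)
        interior = m[50:-50]
        assert np.abs(interior).max() < 0.05

    def test_too_few_extrema_is_trend(self):
        with pytest.raises(SignalIsTrend):
            envelope_mean(np.linspace(0.0, 1.0, 50))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), c=st.floats(-5.0, 5.0))
    def test_antisymmetry_and_shift_equivariance(self, seed, c):
        x = np.random.default_rng(seed).standard_normal(120)
        m = envelope_mean(x)
        np.testing.assert_allclose(envelope_mean(-x), -m, atol=1e-9)
        np.testing.assert_allclose(envelope_mean(x + c), m + c, atol=1e-9)


class TestSift:
    def test_one_iteration_is_definition(self, rng):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(sift(x, 1), x - envelope_mean(x), atol=1e-12)

    def test_pure_tone_is_near_fixed_point(self):
        t = np.arange(500) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        h = sift(x, 10)
        sl = central_slice(len(x))
        r = np.corrcoef(h[sl], x[sl])[0, 1]
        assert r >= 0.99

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), lam=st.floats(0.1, 10.0))
    def test_positive_homogeneity(self, seed, lam):
        x = np.random.default_rng(seed).standard_normal(120)
        np.testing.assert_allclose(
            sift(lam * x, 5), lam * sift(x, 5), rtol=1e-9, atol=1e-9
        )


class TestEMD:
    def test_exact_reconstruction_random_inputs(self):
        for seed in range(10):
            for n in (64, 500, 1024):
                x = np.random.default_rng(seed).standard_normal(n)
                ms = emd(x)
                err = np.abs(ms.reconstruct() - x).max()
                assert err <= 1e-9 * np.abs(x).max()

    def test_two_tone_separation_and_ordering(self):
        hi, lo, t = two_tone()
        ms = emd(hi + lo)
        sl = central_slice(len(t))
        corr_hi = [abs(np.corrcoef(m[sl], hi[sl])[0, 1]) if m[sl].std() > 0 else 0.0
                   for m in ms.modes]
        corr_lo = [abs(np.corrcoef(m[sl], lo[sl])[0, 1]) if m[sl].std() > 0 else 0.0
                   for m in ms.modes]
        j_hi, j_lo = int(np.argmax(corr_hi)), int(np.argmax(corr_lo))
        assert corr_hi[j_hi] >= 0.95 and corr_lo[j_lo] >= 0.95
        assert j_hi != j_lo
        # faster oscillation extracted first
        assert j_hi < j_lo

    def test_zero_input_gives_zero_modes(self):
        ms = emd(np.zeros(500))
        assert ms.n_modes == 8
        assert not np.any(ms.modes)

    def test_modes_are_length_preserving(self, rng):
        x = rng.standard_normal(321)
        assert emd(x).modes.shape == (8, 321)


class TestEEMD:
    def test_zero_noise_ratio_equals_emd(self, rng):
        x = rng.standard_normal(300)
        cfg = EEMDConfig(ensemble_size=7, noise_ratio=0.0, seed=5)
        np.testing.assert_array_equal(eemd(x, cfg).modes, emd(x).modes)

    def test_seeded_determinism_bitwise(self, rng):
        x = rng.standard_normal(300)
        cfg = EEMDConfig(ensemble_size=4, seed=9)
        np.testing.assert_array_equal(eemd(x, cfg).modes, eemd(x, cfg).modes)

    def test_reconstruction_error_bound(self):
        """Residual ensemble noise in RMS stays under 3*noise_ratio*sd/sqrt(E)."""
        E, ratio = 8, 0.2
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(250)
            cfg = EEMDConfig(ensemble_size=E, noise_ratio=ratio, seed=seed)
            err = eemd(x, cfg).reconstruct() - x
            rms = np.sqrt(np.mean(err**2))
            assert rms <= 3.0 * ratio * x.std() / np.sqrt(E)
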