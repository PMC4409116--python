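"""Synthetic EEG generator: determinism, planted components and effects."""

import numpy as np
import pytest

from ermkit import (
    EEGSimConfig,
    EffectSpec,
    WindowDef,
    erp_average,
    one_over_f_noise,
    synth_eeg_dataset,
    synth_subject,
    window_mean_amplitude,
)
from ermkit.pipeline import window_to_samples

N200_EARLY = WindowDef("N200", "early", (150.0, 210.0))


def quiet_config(**kw):
    base = dict(n_subjects=1, channels=["O2", "C4", "F4"],
                n_trials_per_condition=5, noise_sd=0.0,
                band_oscillations=(), seed=1)
    base.update(kw)
    return EEGSimConfig(**base)


class TestDeterministicStructure:
    def test_no_noise_no_effect_gives_identical_erps(self):
        ds = synth_subject(quiet_config(band_oscillations=((10.0, 0.3),)), 0)
        np.testing.assert_array_equal(erp_average(ds, "CT"), erp_average(ds, "NCT"))

    def test_p100_peaks_at_configured_sample_on_posterior_channel(self):
        ds = synth_subject(quiet_config(), 0)
        erp = erp_average(ds, "CT")[0]  # O2, posterior: P100 at 90 ms
        lo, hi = window_to_samples(WindowDef("P100", "early", (60.0, 120.0)), 500.0, 75)
        k = lo + int(np.argmax(erp[lo:hi]))
        assert k == 75 + round(90 * 500 / 1000)

    def test_seed_reproducibility_bitwise(self):
        cfg = EEGSimConfig(n_subjects=2, channels=["O2", "F4"],
                           n_trials_per_condition=4, seed=77)
        a = synth_eeg_dataset(cfg)
        b = synth_eeg_dataset(cfg)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.data, db.data)
            np.testing.assert_array_equal(da.conditions, db.conditions)

    def test_frontal_latency_is_late(self):
        ds = synth_subject(quiet_config(), 0)
        erp_post = erp_average(ds, "CT")[0]   # O2
        erp_front = erp_average(ds, "CT")[2]  # F4
        # N200 trough: posterior at 180 ms, frontal at 230 ms
        t_post = (np.argmin(erp_post[100:260]) + 100 - 75) * 2.0
        t_front = (np.argmin(erp_front[100:260]) + 100 - 75) * 2.0
        assert t_post < t_front


class TestPlantedEffects:
    def test_window_mean_difference_recovers_delta(self):
        delta = -1.0
        cfg = EEGSimConfig(
            n_subjects=1, channels=["O2"], n_trials_per_condition=400,
            noise_sd=1.0, seed=5,
            effect_map=(EffectSpec(("O2",), N200_EARLY, delta),),
        )
        ds = synth_subject(cfg, 0)
        # paired per-trial window means -> closed-form SE of the mean
        lo, hi = window_to_samples(N200_EARLY, 500.0, 75)
        per_trial = ds.data[0, lo:hi, :].mean(axis=0)
        d = per_trial[ds.conditions == "CT"] - per_trial[ds.conditions == "NCT"]
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - delta) <= 3 * se

    def test_effect_confined_to_window(self):
        cfg = quiet_config(channels=["O2"], effect_map=(
            EffectSpec(("O2",), N200_EARLY, -1.0),))
        ds = synth_subject(cfg, 0)
        diff = erp_average(ds, "CT")[0] - erp_average(ds, "NCT")[0]
        inside = window_mean_amplitude(diff, N200_EARLY, 500.0, 75)
        assert inside == pytest.approx(-1.0, abs=1e-9)
        # the effect's support is exactly the planted window's sample range
        lo, hi = window_to_samples(N200_EARLY, 500.0, 75)
        assert not diff[:lo].any() and not diff[hi:].any()
        # zero leak into a disjoint analysis window
        p100 = WindowDef("P100", "early", (60.0, 120.0))
        assert window_mean_amplitude(diff, p100, 500.0, 75) == 0.0

    def test_recovery_error_shrinks_with_trial_count(self):
        """ERP difference converges to the planted delta as 1/sqrt(n_trials)."""
        delta = -1.0
        errs = {}
        for n_tr in (25, 400):
            sq = []
            for seed in range(8):
                cfg = EEGSimConfig(
                    n_subjects=1, channels=["O2"], n_trials_per_condition=n_tr,
                    noise_sd=1.0, seed=seed,
                    effect_map=(EffectSpec(("O2",), N200_EARLY, delta),),
                )
                ds = synth_subject(cfg, 0)
                diff = erp_average(ds, "CT")[0] - erp_average(ds, "NCT")[0]
                est = window_mean_amplitude(diff, N200_EARLY, 500.0, 75)
                sq.append((est - delta) ** 2)
            errs[n_tr] = np.sqrt(np.mean(sq))
        assert errs[400] < errs[25]

    def test_effect_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            WindowDef("N200", "late", (800.0, 900.0))
        with pytest.raises(ValueError):
            quiet_config(effect_map=(
                EffectSpec(("bogus",), N200_EARLY, 1.0),))


class TestNoise:
    def test_one_over_f_noise_is_unit_sd(self, rng):
        x = one_over_f_noise(500, 1.0, rng)
        assert x.std() == pytest.approx(1.0, abs=1e-9)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)

    def test_spectrum_slopes_downward(self, rng):
        # averaged periodogram: low-frequency third carries more power
        ps = np.zeros(251)
        for _ in range(30):
            x = one_over_f_noise(500, 1.0, rng)
            ps += np.abs(np.fft.rfft(x)) ** 2
        low, high = ps[1:80].mean(), ps[170:250].mean()
        assert low > 5 * high
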