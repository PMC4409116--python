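import numpy as np
import pytest

from ermkit import EEGSimConfig, EEMDConfig, StimulusSpec, synth_eeg_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stim_spec():
    return StimulusSpec(path_angle=25.0)


@pytest.fixture
def fast_eemd():
    """Small ensemble for tests where EEMD cost matters more than smoothing."""
    return EEMDConfig(ensemble_size=2, noise_ratio=0.1, seed=3)


@pytest.fixture
def tiny_dataset():
    """4 subjects x 8 channels x 10 trials/condition, quiet noise."""
    cfg = EEGSimConfig(
        n_subjects=4,
        channels=["O1", "O2", "P4", "P8", "C4", "CP4", "F4", "AF4"],
        n_trials_per_condition=10,
        noise_sd=0.5,
        seed=11,
    )
    return synth_eeg_dataset(cfg)


def two_tone(fs=500.0, seconds=2.0, f_hi=25.0, f_lo=3.0):
    """The standard separation benchmark: a fast and a slow cosine."""
    t = np.arange(int(fs * seconds)) / fs
    return np.cos(2 * np.pi * f_hi * t), np.cos(2 * np.pi * f_lo * t), t
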