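"""Hilbert spectral analysis of intrinsic modes (the Hilbert-Huang transform).

Each oscillatory mode c_j(t) is written as the real part of an analytic signal
a_j(t)*exp(i*phi_j(t)); the instantaneous frequency is the derivative of the
unwrapped phase, nu_j(t) = (1/2pi) dphi_j/dt.  The analytic extension is
computed with the FFT-based Hilbert transform.  Instantaneous frequency may be
transiently negative near amplitude nulls; it is reported, not clamped, and
summary statistics exclude the boundary 10% of samples at each end where the
Hilbert transform has edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .emd import ModeSet

__all__ = [
    "HHTSpectrum",
    "analytic_amplitude_phase",
    "instantaneous_frequency",
    "hh_spectrogram",
    "central_slice",
    "band_label",
]

#: canonical EEG band edges in Hz, low-inclusive
_BANDS = (("delta", 0.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0),
          ("beta", 13.0, 30.0), ("gamma", 30.0, np.inf))


def band_label(freq_hz: float) -> str:
    """Map a (mean) frequency to its EEG band name (delta/theta/alpha/beta/gamma)."""
    if freq_hz < 0:
        raise ValueError("band_label expects a non-negative frequency")
    for name, lo, hi in _BANDS:
        if lo <= freq_hz < hi:
            return name
    raise AssertionError("unreachable")


def analytic_amplitude_phase(mode: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and unwrapped phase of the analytic extension."""
    mode = np.asarray(mode, dtype=float)
    if not np.any(mode):
        return np.zeros_like(mode), np.zeros_like(mode)
    z = hilbert(mode)
    return np.abs(z), np.unwrap(np.angle(z))


def instantaneous_frequency(phase: np.ndarray, sample_rate: float) -> np.ndarray:
    """Frequency in Hz from an unwrapped phase series.

    Centered finite differences in the interior, one-sided at the endpoints.
    """
    phase = np.asarray(phase, dtype=float)
    return np.gradient(phase) * sample_rate / (2.0 * np.pi)


def central_slice(n: int, fraction: float = 0.8) -> slice:
    """Slice selecting the central ``fraction`` of ``n`` samples."""
    drop = int(round(n * (1.0 - fraction) / 2.0))
    return slice(drop, n - drop)


@dataclass
class HHTSpectrum:
    """Per-mode instantaneous amplitude/phase/frequency triples.

    Rows of the arrays follow the mode order of the source ModeSet.  The
    residual trend (last mode) carries amplitude only; its phase and frequency
    rows are NaN.
    """

    amplitude: np.ndarray  # (n_modes, n_samples)
    phase: np.ndarray
    frequency: np.ndarray  # Hz
    sample_rate: float

    @property
    def n_modes(self) -> int:
        return self.amplitude.shape[0]

    def mean_frequency(self, mode_index: int, fraction: float = 0.8) -> float:
        """Mean instantaneous frequency over the central fraction of samples."""
        sl = central_slice(self.frequency.shape[1], fraction)
        return float(np.mean(self.frequency[mode_index, sl]))

    def median_frequency(self, mode_index: int, fraction: float = 0.8) -> float:
        sl = central_slice(self.frequency.shape[1], fraction)
        return float(np.median(self.frequency[mode_index, sl]))

    def to_frame(self, onset_index: int = 0) -> pd.DataFrame:
        """Long-format table (mode, sample, time_ms, amplitude, frequency_hz)."""
        n_modes, n = self.amplitude.shape
        t_ms = (np.arange(n) - onset_index) * 1000.0 / self.sample_rate
        frames = []
        for j in range(n_modes):
            frames.append(pd.DataFrame({
                "mode": j + 1,
                "sample": np.arange(n),
                "time_ms": t_ms,
                "amplitude": self.amplitude[j],
                "frequency_hz": self.frequency[j],
            }))
        return pd.concat(frames, ignore_index=True)


def hh_spectrogram(modes: ModeSet) -> HHTSpectrum:
    """Hilbert-Huang spectrum of a ModeSet.

    Oscillatory modes (all but the last) get amplitude, unwrapped phase and
    instantaneous frequency; the residual trend gets amplitude only.
    """
    m, n = modes.modes.shape
    amp = np.zeros((m, n))
    ph = np.full((m, n), np.nan)
    freq = np.full((m, n), np.nan)
    for j in range(m - 1):
        a, p = analytic_amplitude_phase(modes.modes[j])
        amp[j] = a
        ph[j] = p
        freq[j] = instantaneous_frequency(p, modes.sample_rate)
    amp[m - 1] = np.abs(hilbert(modes.modes[m - 1])) if np.any(modes.modes[m - 1]) \
        else np.zeros(n)
    return HHTSpectrum(amplitude=amp, phase=ph, frequency=freq,
                       sample_rate=modes.sample_rate)
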