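"""Empirical mode decomposition with spline envelopes and fixed-iteration sifting.

EMD represents a signal as a sum of intrinsic mode functions (IMFs) plus a
non-oscillating residual trend,

    x(t) = sum_j c_j(t) + r(t),

where each IMF is obtained by *sifting*: repeatedly subtracting the mean of the
cubic-spline envelopes through the local maxima and minima.  Instead of testing
the formal IMF condition, sifting here runs a fixed number of iterations per
mode, and the number of extracted modes is fixed in advance (7 IMFs, with the
residual trend appended as an 8th mode) so that modes can be averaged across
trials and ensemble members.

The ensemble variant (EEMD) decomposes E noise-perturbed copies of the signal,

    x_n(t) = x(t) + eps_n(t),    n = 1..E,

with white Gaussian eps_n of standard deviation ``noise_ratio * std(x)``, and
averages corresponding IMFs over the ensemble.  Averaging suppresses mode
mixing; the residual ensemble noise in each averaged mode shrinks as 1/sqrt(E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Signal",
    "ModeSet",
    "EEMDConfig",
    "SignalIsTrend",
    "find_extrema",
    "envelope_mean",
    "sift",
    "emd",
    "eemd",
]


class SignalIsTrend(ValueError):
    """Raised when a signal has too few extrema to support spline envelopes."""


@dataclass
class Signal:
    """A finite real-valued amplitude series with a sample rate."""

    samples: np.ndarray
    sample_rate: float = 500.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Signal.samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal.samples must be finite")
        if self.samples.size < 8:
            raise ValueError("Signal must have at least 8 samples")


@dataclass
class ModeSet:
    """An ordered decomposition: modes[0..n-2] are IMFs, modes[-1] the trend.

    By convention the residual trend is stored as the last mode, so a
    7-IMF decomposition is stored as 8 modes.
    """

    modes: np.ndarray  # (n_modes, n_samples)
    sample_rate: float = 500.0
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def source_length(self) -> int:
        return self.modes.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.modes.sum(axis=0)


@dataclass
class EEMDConfig:
    """Ensemble EMD parameters.

    ensemble_size
        Number E of noise realizations averaged (default 20).
    noise_ratio
        Std of added white noise relative to the signal std (default 0.2).
    n_imfs
        Number of oscillatory modes extracted; the residual is appended as
        mode ``n_imfs + 1`` (default 7, i.e. 8 stored modes).
    sift_iterations
        Fixed number of sifting iterations per mode (default 10).
    seed
        Seeds all ensemble noise; ensemble member n draws from an independent
        substream derived from (seed, n), so members are order-independent.
    """

    ensemble_size: int = 20
    noise_ratio: float = 0.2
    n_imfs: int = 7
    sift_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_ratio < 0:
            raise ValueError("noise_ratio must be >= 0")
        if self.n_imfs < 1:
            raise ValueError("n_imfs must be >= 1")
        if self.sift_iterations < 1:
            raise ValueError("sift_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "ensemble_size": self.ensemble_size,
            "noise_ratio": self.noise_ratio,
            "n_imfs": self.n_imfs,
            "sift_iterations": self.sift_iterations,
            "seed": self.seed,
        }


# ---------------------------------------------------------------- extrema ----

def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D series.

    A plateau that is a local extremum contributes its first sample.
    Monotone and constant series yield empty index arrays.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    sv = s[nz]
    ch = np.flatnonzero(sv[:-1] != sv[1:])
    # sign flips rise->fall at a maximum, fall->rise at a minimum; the index
    # nz[ch]+1 is the first sample of the peak (or plateau)
    maxima = nz[ch][sv[ch] > 0] + 1
    minima = nz[ch][sv[ch] < 0] + 1
    return maxima.astype(int), minima.astype(int)


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to 2 extrema per side across the signal endpoints."""
    k = min(2, idx.size)
    left_t = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, val, right_v])
    # mirrored knots can coincide with originals when an extremum sits on an
    # endpoint; keep strictly increasing knots
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Pointwise mean of the cubic-spline upper and lower envelopes.

    The signal is mirror-extended by reflecting two extrema at each end before
    spline fitting, which suppresses end swings on short epochs.

    Raises
    ------
    SignalIsTrend
        If there are fewer than 2 maxima or fewer than 2 minima; such a
        signal is treated as a residual trend.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise SignalIsTrend(
            f"need >=2 maxima and minima, found {maxima.size}/{minima.size}"
        )
    grid = np.arange(n)
    tu, vu = _mirror_knots(maxima, x[maxima], n)
    tl, vl = _mirror_knots(minima, x[minima], n)
    upper = CubicSpline(tu, vu)(grid)
    lower = CubicSpline(tl, vl)(grid)
    return 0.5 * (upper + lower)


def sift(x: np.ndarray, iterations: int = 10) -> np.ndarray:
    """Extract one mode candidate by fixed-iteration sifting.

    h_0 = x; h_k = h_{k-1} - envelope_mean(h_{k-1}), repeated ``iterations``
    times.  If the trend condition (too few extrema) triggers on the input
    itself, SignalIsTrend propagates; if it triggers after at least one
    subtraction the current h is returned.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    h = np.asarray(x, dtype=float).copy()
    for k in range(iterations):
        try:
            m = envelope_mean(h)
        except SignalIsTrend:
            if k == 0:
                raise
            return h
        h -= m
    return h


def _has_enough_extrema(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return maxima.size >= 2 and minima.size >= 2


def emd(
    x: np.ndarray,
    n_imfs: int = 7,
    sift_iterations: int = 10,
    sample_rate: float = 500.0,
) -> ModeSet:
    """Plain EMD into ``n_imfs`` modes plus the residual trend as the last mode.

    The running remainder is sifted and subtracted ``n_imfs`` times; whatever
    is left goes into the last slot.  If the remainder runs out of extrema
    early, the remaining mode slots are zero and the trend still goes to the
    last slot, preserving exact additive reconstruction.
    """
    x = np.asarray(x, dtype=float)
    modes = np.zeros((n_imfs + 1, x.size))
    remainder = x.copy()
    for j in range(n_imfs):
        if not _has_enough_extrema(remainder):
            break
        c = sift(remainder, sift_iterations)
        modes[j] = c
        remainder = remainder - c
    modes[n_imfs] = remainder
    return ModeSet(
        modes=modes,
        sample_rate=sample_rate,
        meta={"method": "emd", "n_imfs": n_imfs, "sift_iterations": sift_iterations},
    )


def eemd(x: np.ndarray, cfg: EEMDConfig, sample_rate: float = 500.0) -> ModeSet:
    """Ensemble EMD: average the EMD of E noise-perturbed copies of ``x``.

    Noise for ensemble member n comes from the substream (cfg.seed, n), so the
    result is deterministic given cfg.seed and independent of evaluation
    order.  With noise_ratio == 0 this reduces exactly to plain EMD.
    """
    x = np.asarray(x, dtype=float)
    if cfg.noise_ratio == 0.0:
        ms = emd(x, cfg.n_imfs, cfg.sift_iterations, sample_rate)
        ms.meta = {"method": "eemd", **cfg.to_dict()}
        return ms
    sigma = cfg.noise_ratio * float(np.std(x))
    acc = np.zeros((cfg.n_imfs + 1, x.size))
    for n in range(cfg.ensemble_size):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(n,))
        )
        noisy = x + rng.normal(0.0, sigma, size=x.size)
        acc += emd(noisy, cfg.n_imfs, cfg.sift_iterations, sample_rate).modes
    acc /= cfg.ensemble_size
    return ModeSet(modes=acc, sample_rate=sample_rate, meta={"method": "eemd", **cfg.to_dict()})
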