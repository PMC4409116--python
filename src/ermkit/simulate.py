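"""Synthetic multi-subject event-related EEG with known planted effects.

Each trial is the sum of

* Gaussian-windowed ERP deflections (P100 positive, N200 negative, P300
  positive, N400 negative).  Posterior channels (occipital/parietal/
  parieto-temporal clusters) receive the early component latencies, frontal
  channels (frontal/anterior-temporal) the late ones, and central channels
  both at half amplitude, emulating the early-to-late posterior-to-frontal
  progression of visual evoked responses;
* band-limited oscillations near 25, 10, 5 and 2 Hz (beta/alpha/theta/delta)
  with a random phase per trial;
* 1/f background noise, independent per channel and trial;
* condition effects: for trials of the configured condition (CT by default),
  a Gaussian bump confined to a stated latency window on stated channels,
  scaled so the window-mean amplitude difference between conditions equals
  the configured delta exactly.

All randomness derives from a single seed (one substream per subject), so a
dataset is bit-reproducible.  The ground truth (full config and effect map)
travels with each subject's TrialTensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from . import layout as _layout
from .pipeline import CONDITIONS, TrialTensor, WindowDef, window_to_samples

__all__ = [
    "ComponentSpec",
    "EffectSpec",
    "EEGSimConfig",
    "DEFAULT_COMPONENTS",
    "DEFAULT_BANDS",
    "one_over_f_noise",
    "component_waveform",
    "effect_waveform",
    "synth_subject",
    "synth_eeg_dataset",
]

#: channel groups by scalp region, from the cluster assignment
GROUPS = ("posterior", "central", "frontal")


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: Gaussian bump amplitude/latency/width.

    ``latency_ms`` maps each channel group to the latencies (ms after onset)
    at which the bump appears there; a group receiving several latencies
    (the bimodal central channels) splits the amplitude evenly among them.
    """

    name: str
    amplitude: float                       # a.u., sign carries polarity
    width_ms: float                        # Gaussian sd is width_ms / 4
    latency_ms: dict[str, tuple[float, ...]]


@dataclass(frozen=True)
class EffectSpec:
    """A planted condition effect: window-mean delta on a set of channels."""

    channels: tuple[str, ...]
    window: WindowDef
    delta: float
    condition: str = "CT"


DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("P100", 1.0, 45.0,
                  {"posterior": (90.0,), "frontal": (160.0,),
                   "central": (90.0, 160.0)}),
    ComponentSpec("N200", -1.2, 55.0,
                  {"posterior": (180.0,), "frontal": (230.0,),
                   "central": (180.0, 230.0)}),
    ComponentSpec("P300", 0.8, 70.0,
                  {"posterior": (320.0,), "frontal": (320.0,),
                   "central": (320.0,)}),
    ComponentSpec("N400", -0.6, 80.0,
                  {"posterior": (410.0,), "frontal": (410.0,),
                   "central": (410.0,)}),
)

#: (center frequency Hz, amplitude a.u.) near the beta/alpha/theta/delta bands
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (25.0, 0.12), (10.0, 0.3), (5.0, 0.35), (2.0, 0.3),
)


@dataclass
class EEGSimConfig:
    """Study-scale defaults: 18 subjects x 62 channels x 115 trials/condition
    at 500 samples/s, epochs of 75 + 425 samples (-150 to +850 ms)."""

    n_subjects: int = 18
    channels: list[str] = dfield(
        default_factory=lambda: _layout.default_layout()["label"].tolist()
    )
    n_trials_per_condition: int = 115
    sample_rate: float = 500.0
    pre_samples: int = 75
    post_samples: int = 425
    components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS
    band_oscillations: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    noise_exponent: float = 1.0
    # single-trial background noise dominates the evoked response (per-trial
    # SNR ~ 0.25), as in real ERP recordings where components only emerge
    # after trial averaging
    noise_sd: float = 4.0
    effect_map: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial")
        if self.pre_samples < 0 or self.post_samples <= 0:
            raise ValueError("invalid epoch geometry")
        n = self.n_samples
        for eff in self.effect_map:
            lo, hi = window_to_samples(eff.window, self.sample_rate, self.pre_samples)
            if lo < 0 or hi > n:
                raise ValueError(
                    f"effect window {eff.window.interval} outside the epoch"
                )
            unknown = set(eff.channels) - set(self.channels)
            if unknown:
                raise ValueError(f"effect on unknown channels: {sorted(unknown)}")
            if eff.condition not in CONDITIONS:
                raise ValueError(f"unknown effect condition {eff.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.pre_samples + self.post_samples

    def time_ms(self) -> np.ndarray:
        """Per-sample time in ms relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.pre_samples) \
            * 1000.0 / self.sample_rate


def _channel_group(channel: str) -> str:
    lay = _layout.default_layout()
    if channel in _layout.posterior_channels(lay):
        return "posterior"
    if channel in _layout.frontal_channels(lay):
        return "frontal"
    return "central"


def one_over_f_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-sd noise with amplitude spectrum proportional to f^(-exponent/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # leave DC finite; it is removed by the sd normalization anyway
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def component_waveform(cfg: EEGSimConfig, channel: str) -> np.ndarray:
    """Deterministic evoked waveform of one channel (no noise, no effects)."""
    t = cfg.time_ms()
    group = _channel_group(channel)
    out = np.zeros(cfg.n_samples)
    for comp in cfg.components:
        lats = comp.latency_ms.get(group, ())
        if not lats:
            continue
        amp = comp.amplitude / len(lats)
        sd = comp.width_ms / 4.0
        for lat in lats:
            out += amp * np.exp(-((t - lat) ** 2) / (2.0 * sd * sd))
    return out


def effect_waveform(cfg: EEGSimConfig, eff: EffectSpec) -> np.ndarray:
    """Additive effect series whose window mean equals ``eff.delta``.

    A flat-topped tapered-cosine (Tukey) pulse whose support is exactly the
    stated window, so nothing leaks into adjacent (possibly overlapping)
    analysis windows.  The flat top keeps the pulse's peak close to the
    window-mean delta, which keeps the effect's contribution to the epoch
    variance small — a tall narrow bump of equal window mean would visibly
    rescale every other window after z-scoring.
    """
    from scipy.signal.windows import tukey

    lo, hi = window_to_samples(eff.window, cfg.sample_rate, cfg.pre_samples)
    bump = np.zeros(cfg.n_samples)
    shape = tukey(hi - lo, alpha=0.5)
    bump[lo:hi] = shape / shape.mean() * eff.delta
    return bump


def synth_subject(cfg: EEGSimConfig, subject_index: int) -> TrialTensor:
    """Simulate one subject's TrialTensor from substream (seed, subject)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject_index,))
    )
    n_ch = len(cfg.channels)
    n_s = cfg.n_samples
    n_tpc = cfg.n_trials_per_condition
    n_tr = 2 * n_tpc
    # trials stored as the CT block followed by the NCT block; presentation
    # order is irrelevant to the analysis, and blockwise storage keeps the
    # noise-free CT and NCT ERPs bitwise identical
    conditions = np.array(["CT"] * n_tpc + ["NCT"] * n_tpc, dtype=object)

    base = np.stack([component_waveform(cfg, ch) for ch in cfg.channels])
    effects = np.zeros((2, n_ch, n_s))  # per condition
    for eff in cfg.effect_map:
        # conditions are modulated symmetrically (+/- delta/2 around the
        # shared mean waveform): the stated condition's window mean exceeds
        # the other's by exactly delta, and both conditions carry the same
        # effect variance, so per-epoch z-scoring treats them alike
        wave = 0.5 * effect_waveform(cfg, eff)
        ki = CONDITIONS.index(eff.condition)
        for ch in eff.channels:
            effects[ki, cfg.channels.index(ch)] += wave
            effects[1 - ki, cfg.channels.index(ch)] -= wave

    t_s = np.arange(n_s) / cfg.sample_rate
    data = np.empty((n_ch, n_s, n_tr))
    for j in range(n_tpc):
        # band phases are drawn once per trial pair and shared between the
        # j-th CT and j-th NCT trial, so the oscillatory background cancels
        # exactly in the condition difference
        osc = np.zeros(n_s)
        for f_hz, amp in cfg.band_oscillations:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc += amp * np.sin(2.0 * np.pi * f_hz * t_s + phase)
        for ki in range(2):
            trial = base + effects[ki] + osc[None, :]
            if cfg.noise_sd > 0:
                noise = np.stack([
                    one_over_f_noise(n_s, cfg.noise_exponent, rng)
                    for _ in range(n_ch)
                ])
                trial = trial + cfg.noise_sd * noise
            data[:, :, ki * n_tpc + j] = trial

    return TrialTensor(
        subject_id=f"S{subject_index + 1:02d}",
        channels=list(cfg.channels),
        data=data,
        conditions=conditions,
        sample_rate=cfg.sample_rate,
        onset_index=cfg.pre_samples,
        ground_truth={
            "seed": cfg.seed,
            "subject_index": subject_index,
            "effects": [
                {
                    "channels": list(e.channels),
                    "component": e.window.component,
                    "phase": e.window.phase,
                    "interval_ms": list(e.window.interval),
                    "delta": e.delta,
                    "condition": e.condition,
                }
                for e in cfg.effect_map
            ],
        },
    )


def synth_eeg_dataset(cfg: EEGSimConfig) -> list[TrialTensor]:
    """Simulate the full multi-subject dataset (one TrialTensor per subject)."""
    return [synth_subject(cfg, i) for i in range(cfg.n_subjects)]
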