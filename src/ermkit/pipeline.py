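"""Event-related mode analysis of multi-trial EEG.

The pipeline mirrors a standard event-related design: epochs of 500 samples at
500 samples/s span -150 to +850 ms around stimulus onset (75 pre-stimulus
samples, onset at index 75).  Per-channel event-related potentials (ERPs) are
trial averages within each stimulus condition (CT = contour, NCT =
non-contour).  Event-related modes (ERMs) are obtained by ensemble empirical
mode decomposition in one of two ways:

    A. decompose the per-condition ERP of each channel (phase-locked activity
       only), or
    B. decompose every standardized single trial and average the resulting
       modes over trials per condition (includes non-phase-locked activity).

All signals are standardized to zero mean and unit variance before
decomposition.  Condition effects are quantified per channel as the group mean
of |mean amplitude(CT)| - |mean amplitude(NCT)| within fixed latency windows
around the ERP components (P100 early 60-120 ms / late 120-180 ms; N200 early
150-210 ms / late 200-260 ms), tested with a two-sided paired t-test across
subjects at alpha in {0.05, 0.01, 0.001}.  No multiple-comparison correction
is applied; results are reported per channel.  Channels can be pooled into
six scalp clusters per hemisphere, and per-channel statistics laid out as
head topographies with a significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .emd import EEMDConfig, ModeSet, eemd
from .layout import CLUSTERS

__all__ = [
    "CONDITIONS",
    "TrialTensor",
    "WindowDef",
    "DEFAULT_WINDOWS",
    "ERMSet",
    "ChannelStat",
    "segment_epoch",
    "standardize",
    "erp_average",
    "erms_approach_A",
    "erms_approach_B",
    "window_to_samples",
    "window_mean_amplitude",
    "condition_difference_stats",
    "significance_tier",
    "pool_electrodes",
    "peak_latency_ms",
    "topography_values",
    "interpolate_topography",
    "stats_to_frame",
]

CONDITIONS = ("CT", "NCT")


@dataclass
class TrialTensor:
    """One subject's epoched EEG: channels x samples x trials with labels."""

    subject_id: str
    channels: list[str]
    data: np.ndarray           # (n_channels, n_samples, n_trials)
    conditions: np.ndarray     # (n_trials,) of 'CT'/'NCT'
    sample_rate: float = 500.0
    onset_index: int = 75
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} rows"
            )
        if self.conditions.shape[0] != self.data.shape[2]:
            raise ValueError("every trial needs a condition label")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(map(str, bad))}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data must be finite")
        if not 0 <= self.onset_index < self.data.shape[1]:
            raise ValueError("onset_index outside the epoch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def trials_of(self, condition: str) -> np.ndarray:
        """(n_channels, n_samples, n_cond_trials) view for one condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask = self.conditions == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return self.data[:, :, mask]


@dataclass(frozen=True)
class WindowDef:
    """A latency window (ms relative to stimulus onset) of an ERP component."""

    component: str   # P100 / N200 / P300 / N400
    phase: str       # early / late
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (-150.0 <= lo < hi <= 850.0):
            raise ValueError(f"window {self.interval} outside the epoch")

    @property
    def name(self) -> str:
        return f"{self.component}_{self.phase}"


DEFAULT_WINDOWS: tuple[WindowDef, ...] = (
    WindowDef("P100", "early", (60.0, 120.0)),
    WindowDef("P100", "late", (120.0, 180.0)),
    WindowDef("N200", "early", (150.0, 210.0)),
    WindowDef("N200", "late", (200.0, 260.0)),
)


@dataclass
class ERMSet:
    """Per-channel, per-condition event-related modes.

    ``modes`` has shape (n_channels, 2 conditions, n_modes, n_samples) with
    the condition axis ordered (CT, NCT) and the residual trend last on the
    mode axis.
    """

    channels: list[str]
    modes: np.ndarray
    approach: str              # 'A' or 'B'
    eemd_config: dict
    sample_rate: float = 500.0
    onset_index: int = 75
    erps: np.ndarray | None = None  # standardized ERPs, (n_channels, 2, n_samples)

    def __post_init__(self) -> None:
        if self.approach not in ("A", "B"):
            raise ValueError("approach must be 'A' or 'B'")
        if self.modes.ndim != 4 or self.modes.shape[1] != 2:
            raise ValueError("modes must be channels x 2 conditions x modes x samples")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[2]

    def mode(self, channel: str, condition: str, mode_index: int) -> np.ndarray:
        """One mode series; ``mode_index`` is 1-based (mode 8 = residual trend)."""
        ci = self.channels.index(channel)
        si = CONDITIONS.index(condition)
        return self.modes[ci, si, mode_index - 1]


@dataclass
class ChannelStat:
    """Per-channel paired-test result for one window and one signal source.

    ``mode_index`` is the 1-based mode number, or None for the raw ERP.
    ``mean_diff`` is the group mean of |amp_CT| - |amp_NCT| (CT - NCT sign
    convention, so NCT-dominant channels get negative T).
    """

    channel: str
    window: WindowDef
    mean_diff: float
    t_value: float
    p_value: float
    tier: str
    mode_index: int | None = None
    n_subjects: int = 0


# -------------------------------------------------------------- epoching ----

def segment_epoch(
    series: np.ndarray, onset: int, pre: int = 75, post: int = 425
) -> np.ndarray:
    """Cut a pre+post epoch from a continuous series around ``onset``.

    The epoch covers samples [onset - pre, onset + post); its sample ``pre``
    is the onset sample.
    """
    series = np.asarray(series, dtype=float)
    if onset - pre < 0 or onset + post > series.shape[-1]:
        raise ValueError(
            f"epoch [{onset - pre}, {onset + post}) outside series of "
            f"length {series.shape[-1]}"
        )
    return series[..., onset - pre : onset + post].copy()


def standardize(epoch: np.ndarray) -> np.ndarray:
    """z-score an epoch to zero mean and unit variance (population sd)."""
    epoch = np.asarray(epoch, dtype=float)
    sd = float(np.std(epoch))
    if sd == 0.0 or np.ptp(epoch) == 0.0:
        raise ValueError("cannot standardize a constant epoch")
    return (epoch - float(np.mean(epoch))) / sd


def erp_average(trials: TrialTensor, condition: str) -> np.ndarray:
    """Per-channel ERP: samplewise trial mean within one condition.

    Returns an (n_channels, n_samples) array.
    """
    return trials.trials_of(condition).mean(axis=2)


# ------------------------------------------------------------------ ERMs ----

def erms_approach_A(trials: TrialTensor, cfg: EEMDConfig) -> ERMSet:
    """Decompose per-condition ERPs: standardize, then EEMD, per channel.

    Keeps only activity phase-locked to the stimulus.
    """
    n_ch, n_s = trials.n_channels, trials.n_samples
    modes = np.zeros((n_ch, 2, cfg.n_imfs + 1, n_s))
    erps = np.zeros((n_ch, 2, n_s))
    for si, cond in enumerate(CONDITIONS):
        erp = erp_average(trials, cond)
        for ci in range(n_ch):
            z = standardize(erp[ci])
            erps[ci, si] = z
            modes[ci, si] = eemd(z, cfg, trials.sample_rate).modes
    return ERMSet(
        channels=list(trials.channels),
        modes=modes,
        approach="A",
        eemd_config=cfg.to_dict(),
        sample_rate=trials.sample_rate,
        onset_index=trials.onset_index,
        erps=erps,
    )


def erms_approach_B(
    trials: TrialTensor, cfg: EEMDConfig, share_noise: bool = True
) -> ERMSet:
    """Decompose every standardized single trial, then average modes per
    condition.

    Retains non-phase-locked activity as well.  With ``share_noise`` (default)
    every trial's ensemble uses the same noise substreams (cfg.seed), making
    the identical-trials degenerate case agree with approach A exactly; with
    ``share_noise=False`` each trial draws an independent substream.
    """
    n_ch, n_s = trials.n_channels, trials.n_samples
    modes = np.zeros((n_ch, 2, cfg.n_imfs + 1, n_s))
    erps = np.zeros((n_ch, 2, n_s))
    for si, cond in enumerate(CONDITIONS):
        block = trials.trials_of(cond)
        n_tr = block.shape[2]
        for ci in range(n_ch):
            acc = np.zeros((cfg.n_imfs + 1, n_s))
            for k in range(n_tr):
                z = standardize(block[ci, :, k])
                trial_cfg = cfg if share_noise else EEMDConfig(
                    ensemble_size=cfg.ensemble_size,
                    noise_ratio=cfg.noise_ratio,
                    n_imfs=cfg.n_imfs,
                    sift_iterations=cfg.sift_iterations,
                    seed=int(
                        np.random.SeedSequence(
                            entropy=cfg.seed, spawn_key=(si, ci, k)
                        ).generate_state(1)[0] % (2**31)
                    ),
                )
                acc += eemd(z, trial_cfg, trials.sample_rate).modes
            modes[ci, si] = acc / n_tr
            erps[ci, si] = standardize(erp_average(trials, cond)[ci])
    return ERMSet(
        channels=list(trials.channels),
        modes=modes,
        approach="B",
        eemd_config=cfg.to_dict(),
        sample_rate=trials.sample_rate,
        onset_index=trials.onset_index,
        erps=erps,
    )


# ------------------------------------------------------ window statistics ----

def window_to_samples(
    window: WindowDef, sample_rate: float, onset_index: int
) -> tuple[int, int]:
    """Half-open sample range [lo, hi) of a latency window.

    ms -> sample mapping: sample = onset_index + round(ms * rate / 1000),
    round-half-up, so counts are bit-stable.
    """
    lo_ms, hi_ms = window.interval
    lo = onset_index + int(np.floor(lo_ms * sample_rate / 1000.0 + 0.5))
    hi = onset_index + int(np.floor(hi_ms * sample_rate / 1000.0 + 0.5))
    if hi <= lo:
        raise ValueError(f"window {window.interval} maps to an empty sample range")
    return lo, hi


def window_mean_amplitude(
    series: np.ndarray, window: WindowDef, sample_rate: float, onset_index: int
) -> float:
    """Arithmetic mean of the samples inside a latency window."""
    series = np.asarray(series, dtype=float)
    lo, hi = window_to_samples(window, sample_rate, onset_index)
    if lo < 0 or hi > series.shape[-1]:
        raise ValueError("window outside the epoch")
    return float(series[..., lo:hi].mean())


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def condition_difference_stats(
    amp_ct: np.ndarray,
    amp_nct: np.ndarray,
    channels: list[str],
    window: WindowDef,
    mode_index: int | None = None,
) -> list[ChannelStat]:
    """Channel-wise paired t-tests of |amp_CT| - |amp_NCT| across subjects.

    ``amp_ct`` and ``amp_nct`` are (n_subjects, n_channels) arrays of signed
    window-mean amplitudes; absolute values are taken here.  The test is
    two-sided against zero; significance tiers are assigned at alpha in
    {0.05, 0.01, 0.001}.  No multiple-comparison correction is applied.
    """
    amp_ct = np.atleast_2d(np.asarray(amp_ct, dtype=float))
    amp_nct = np.atleast_2d(np.asarray(amp_nct, dtype=float))
    if amp_ct.shape != amp_nct.shape:
        raise ValueError("amplitude arrays must have matching shapes")
    n_subj, n_ch = amp_ct.shape
    if n_subj < 2:
        raise ValueError("paired test requires at least 2 subjects")
    if n_ch != len(channels):
        raise ValueError("channel labels do not match amplitude columns")
    d = np.abs(amp_ct) - np.abs(amp_nct)
    out = []
    for ci, ch in enumerate(channels):
        di = d[:, ci]
        sd = float(np.std(di, ddof=1))
        if sd == 0.0:
            m = float(np.mean(di))
            t = 0.0 if m == 0.0 else np.inf * np.sign(m)
            p = 1.0 if m == 0.0 else 0.0
        else:
            t, p = sstats.ttest_rel(np.abs(amp_ct[:, ci]), np.abs(amp_nct[:, ci]))
            t, p = float(t), float(p)
        out.append(
            ChannelStat(
                channel=ch,
                window=window,
                mean_diff=float(np.mean(di)),
                t_value=t,
                p_value=p,
                tier=significance_tier(p),
                mode_index=mode_index,
                n_subjects=n_subj,
            )
        )
    return out


def stats_to_frame(stats: list[ChannelStat]) -> pd.DataFrame:
    """Tabulate ChannelStats (ERM, window, p/T, channel, tier) as a DataFrame."""
    return pd.DataFrame(
        {
            "source": ["ERP" if s.mode_index is None else f"ERM{s.mode_index}"
                       for s in stats],
            "component": [s.window.component for s in stats],
            "phase": [s.window.phase for s in stats],
            "channel": [s.channel for s in stats],
            "mean_diff": [s.mean_diff for s in stats],
            "t_value": [s.t_value for s in stats],
            "p_value": [s.p_value for s in stats],
            "tier": [s.tier for s in stats],
            "n_subjects": [s.n_subjects for s in stats],
        }
    )


# ----------------------------------------------------- pooling/topography ----

def pool_electrodes(
    erms: ERMSet,
    layout: pd.DataFrame,
    cluster: str,
    mode_index: int | None = 5,
    hemisphere: str | None = None,
) -> dict[str, np.ndarray]:
    """Samplewise mean of one mode over a cluster's channels, per condition.

    ``mode_index`` is 1-based; None pools the mode sum (the reconstructed
    signal).  ``hemisphere`` ('L'/'R') restricts the pool; midline channels
    belong to neither hemisphere.  Returns {'CT': series, 'NCT': series}.
    """
    if cluster not in CLUSTERS:
        raise ValueError(f"unknown cluster {cluster!r}")
    sel = layout[layout["cluster"] == cluster]
    if hemisphere is not None:
        sel = sel[sel["hemisphere"] == hemisphere]
    labels = [ch for ch in sel["label"] if ch in erms.channels]
    if not labels:
        raise ValueError(f"cluster {cluster!r} has no channels in this ERMSet")
    out = {}
    for cond in CONDITIONS:
        if mode_index is None:
            series = [
                erms.modes[erms.channels.index(ch), CONDITIONS.index(cond)].sum(axis=0)
                for ch in labels
            ]
        else:
            series = [erms.mode(ch, cond, mode_index) for ch in labels]
        out[cond] = np.mean(series, axis=0)
    return out


def peak_latency_ms(
    series: np.ndarray,
    sample_rate: float,
    onset_index: int,
    search_ms: tuple[float, float] = (0.0, 400.0),
    polarity: str = "abs",
) -> float:
    """Latency (ms after onset) of the extremum within a search window.

    ``polarity``: 'pos' for a positive peak, 'neg' for a negative one,
    'abs' for the largest magnitude.
    """
    lo = onset_index + int(np.floor(search_ms[0] * sample_rate / 1000.0 + 0.5))
    hi = onset_index + int(np.floor(search_ms[1] * sample_rate / 1000.0 + 0.5))
    seg = np.asarray(series, dtype=float)[lo:hi]
    if polarity == "pos":
        k = int(np.argmax(seg))
    elif polarity == "neg":
        k = int(np.argmin(seg))
    else:
        k = int(np.argmax(np.abs(seg)))
    return (lo + k - onset_index) * 1000.0 / sample_rate


def topography_values(
    stats: list[ChannelStat], layout: pd.DataFrame
) -> pd.DataFrame:
    """Per-channel scalar map (group mean difference) with significance mask.

    Every layout channel must be covered by ``stats``; missing channels are
    reported, not silently dropped.
    """
    by_ch = {s.channel: s for s in stats}
    missing = [ch for ch in layout["label"] if ch not in by_ch]
    if missing:
        raise ValueError(f"stats missing for channels: {missing}")
    rows = []
    for _, r in layout.iterrows():
        s = by_ch[r["label"]]
        rows.append((r["label"], r["x"], r["y"], s.mean_diff, s.tier != "ns"))
    return pd.DataFrame(rows, columns=["label", "x", "y", "value", "significant"])


def interpolate_topography(
    topo: pd.DataFrame, grid_n: int = 64, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance interpolation of channel values onto a square grid.

    At a channel's own position the interpolant reproduces the channel value
    exactly.  Intended for plotting head maps.
    """
    xs = topo["x"].to_numpy(float)
    ys = topo["y"].to_numpy(float)
    vs = topo["value"].to_numpy(float)
    gx = np.linspace(xs.min(), xs.max(), grid_n)
    gy = np.linspace(ys.min(), ys.max(), grid_n)
    out = np.zeros((grid_n, grid_n))
    for i, yy in enumerate(gy):
        d2 = (gx[None, :] - xs[:, None]) ** 2 + (yy - ys[:, None]) ** 2
        hit = d2 < 1e-18
        w = 1.0 / np.power(d2, power / 2.0, where=~hit, out=np.full_like(d2, np.inf))
        col_hit = hit.any(axis=0)
        out[i] = (w * vs[:, None]).sum(axis=0) / w.sum(axis=0)
        if col_hit.any():
            idx = hit.argmax(axis=0)
            out[i, col_hit] = vs[idx[col_hit]]
    return out


def subject_window_amplitudes(
    ermsets: list[ERMSet],
    window: WindowDef,
    mode_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Signed window-mean amplitudes per subject and channel.

    ``mode_index`` selects an ERM (1-based); None uses the standardized raw
    ERP stored on each ERMSet.  Returns (amp_CT, amp_NCT, channels), each
    amplitude array (n_subjects, n_channels).
    """
    if not ermsets:
        raise ValueError("need at least one subject")
    channels = ermsets[0].channels
    n_subj = len(ermsets)
    amp = np.zeros((2, n_subj, len(channels)))
    for si, es in enumerate(ermsets):
        if es.channels != channels:
            raise ValueError("subjects have differing channel sets")
        for ki, cond in enumerate(CONDITIONS):
            for ci, ch in enumerate(channels):
                if mode_index is None:
                    if es.erps is None:
                        raise ValueError("ERMSet carries no raw ERPs")
                    series = es.erps[ci, ki]
                else:
                    series = es.mode(ch, cond, mode_index)
                amp[ki, si, ci] = window_mean_amplitude(
                    series, window, es.sample_rate, es.onset_index
                )
    return amp[0], amp[1], channels
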