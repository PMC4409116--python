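"""Readers, writers and the end-to-end pipeline runner.

Primary interchange formats are plain text: delimited numeric matrices with a
JSON sidecar (trial tensors), delimited matrices with a commented JSON header
(mode sets, topography grids) and TSV tables with a commented JSON header
(channel statistics, pooled modes).  Every writer emits a format-versioned
header carrying the run configuration and seed; readers reject unknown
versions.  Given the same configuration and seed, all output files are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import layout as _layout
from .emd import EEMDConfig, ModeSet
from .pipeline import (
    CONDITIONS,
    ChannelStat,
    DEFAULT_WINDOWS,
    ERMSet,
    TrialTensor,
    WindowDef,
    condition_difference_stats,
    erms_approach_A,
    erms_approach_B,
    pool_electrodes,
    stats_to_frame,
    subject_window_amplitudes,
    topography_values,
)
from .simulate import EEGSimConfig, EffectSpec, synth_eeg_dataset

__all__ = [
    "FORMAT_VERSION",
    "RunConfig",
    "PipelineResult",
    "read_trials",
    "write_trials",
    "read_modeset",
    "write_modeset",
    "run_pipeline",
]

FORMAT_VERSION = 1

log = logging.getLogger("ermkit")


def _check_version(header: dict, what: str) -> None:
    v = header.get("format_version")
    if v != FORMAT_VERSION:
        raise ValueError(f"{what}: unsupported format version {v!r}")


# ------------------------------------------------------------ trial files ----

def write_trials(path: str | Path, trials: TrialTensor) -> None:
    """Write a TrialTensor as <path> (matrix) + <path>.json (sidecar).

    The matrix is channels x (samples * trials), trials concatenated along
    the columns.
    """
    path = Path(path)
    mat = trials.data.transpose(0, 2, 1).reshape(trials.n_channels, -1)
    np.savetxt(path, mat, fmt="%.17g", delimiter="\t")
    sidecar = {
        "format_version": FORMAT_VERSION,
        "subject_id": trials.subject_id,
        "channels": trials.channels,
        "n_samples": trials.n_samples,
        "n_trials": trials.n_trials,
        "sample_rate": trials.sample_rate,
        "onset_index": trials.onset_index,
        "conditions": [str(c) for c in trials.conditions],
        "ground_truth": trials.ground_truth,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_trials(path: str | Path, sidecar: str | Path | None = None) -> TrialTensor:
    """Read a TrialTensor written by :func:`write_trials`.

    Dimension mismatches, unknown condition labels and non-finite values are
    each reported distinctly (by TrialTensor validation).
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    _check_version(meta, str(sidecar))
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    n_ch = len(meta["channels"])
    n_s, n_t = meta["n_samples"], meta["n_trials"]
    if mat.shape != (n_ch, n_s * n_t):
        raise ValueError(
            f"{path}: matrix is {mat.shape}, sidecar declares "
            f"({n_ch}, {n_s}*{n_t})"
        )
    data = mat.reshape(n_ch, n_t, n_s).transpose(0, 2, 1)
    return TrialTensor(
        subject_id=meta["subject_id"],
        channels=list(meta["channels"]),
        data=data,
        conditions=np.array(meta["conditions"], dtype=object),
        sample_rate=meta["sample_rate"],
        onset_index=meta["onset_index"],
        ground_truth=meta.get("ground_truth", {}),
    )


# ------------------------------------------------------------- mode files ----

def write_modeset(path: str | Path, modes: ModeSet) -> None:
    """Write a ModeSet as a modes x samples matrix with a JSON header line."""
    header = json.dumps(
        {"format_version": FORMAT_VERSION, "sample_rate": modes.sample_rate,
         **modes.meta},
        sort_keys=True,
    )
    np.savetxt(path, modes.modes, fmt="%.17g", delimiter="\t", header=header)


def read_modeset(path: str | Path) -> ModeSet:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing header line")
    meta = json.loads(first[1:].strip())
    _check_version(meta, str(path))
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    rate = meta.pop("sample_rate")
    meta.pop("format_version")
    return ModeSet(modes=mat, sample_rate=rate, meta=meta)


# -------------------------------------------------------------- run config ----

@dataclass
class RunConfig:
    """Everything one end-to-end analysis needs; fully YAML-serializable."""

    seed: int = 0
    approach: str = "A"
    eemd: EEMDConfig = field(default_factory=EEMDConfig)
    windows: tuple[WindowDef, ...] = DEFAULT_WINDOWS
    modes_of_interest: tuple[int, ...] = (4, 5, 6, 7)
    pooling_mode: int = 5
    layout_path: str | None = None
    simulate: EEGSimConfig | None = None
    trial_files: tuple[str, ...] = ()
    output_dir: str = "ermkit_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.approach not in ("A", "B"):
            raise ValueError("approach must be 'A' or 'B'")
        if self.simulate is None and not self.trial_files:
            # callers may still inject datasets directly into run_pipeline
            pass

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = [
            {"component": w.component, "phase": w.phase, "interval": list(w.interval)}
            for w in self.windows
        ]
        if self.simulate is not None:
            sim = d["simulate"]
            sim["components"] = [
                {"name": c.name, "amplitude": c.amplitude, "width_ms": c.width_ms,
                 "latency_ms": {g: list(v) for g, v in c.latency_ms.items()}}
                for c in self.simulate.components
            ]
            sim["effect_map"] = [
                {"channels": list(e.channels), "component": e.window.component,
                 "phase": e.window.phase, "interval": list(e.window.interval),
                 "delta": e.delta, "condition": e.condition}
                for e in self.simulate.effect_map
            ]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "eemd" in kwargs:
            kwargs["eemd"] = EEMDConfig(**kwargs["eemd"])
        if "windows" in kwargs:
            kwargs["windows"] = tuple(
                WindowDef(w["component"], w["phase"], tuple(w["interval"]))
                for w in kwargs["windows"]
            )
        if kwargs.get("simulate"):
            sim = dict(kwargs["simulate"])
            if "effect_map" in sim:
                sim["effect_map"] = tuple(
                    EffectSpec(
                        channels=tuple(e["channels"]),
                        window=WindowDef(e["component"], e["phase"],
                                         tuple(e["interval"])),
                        delta=e["delta"],
                        condition=e.get("condition", "CT"),
                    )
                    for e in sim["effect_map"]
                )
            sim.pop("components", None)  # component overrides not supported in YAML
            kwargs["simulate"] = EEGSimConfig(**sim)
        for tup_key in ("modes_of_interest", "trial_files"):
            if tup_key in kwargs:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    config: RunConfig
    ermsets: list[ERMSet]
    stats: list[ChannelStat]
    pooled: dict[tuple[str, str], np.ndarray]  # (cluster, condition) -> series
    topographies: dict[str, pd.DataFrame]      # "source/component_phase" -> map

    def stats_frame(self) -> pd.DataFrame:
        return stats_to_frame(self.stats)


def _tsv_header(config: RunConfig) -> str:
    return "# " + json.dumps(
        {"format_version": FORMAT_VERSION, "seed": config.seed,
         "config": config.to_dict()},
        sort_keys=True, default=str,
    ) + "\n"


def _write_table(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig,
    datasets: list[TrialTensor] | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the full analysis: data -> ERMs -> window stats -> pooling/maps.

    Input comes from ``datasets`` if given, else from ``config.simulate``,
    else from ``config.trial_files``.  Deterministic given config + seed;
    with ``write_outputs`` the stats, pooled-mode and topography tables are
    written under ``config.output_dir``, every file carrying the config echo
    and seed in its header.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    t0 = time.perf_counter()

    if datasets is None:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            datasets = synth_eeg_dataset(sim)
        elif config.trial_files:
            datasets = [read_trials(p) for p in config.trial_files]
        else:
            raise ValueError("no input: provide datasets, simulate or trial_files")
    log.info("stage input: %d subjects (%.1fs)", len(datasets),
             time.perf_counter() - t0)

    layout = (_layout.load_layout(config.layout_path) if config.layout_path
              else _layout.default_layout())
    layout = layout[layout["label"].isin(datasets[0].channels)].reset_index(drop=True)

    cfg = dataclasses.replace(config.eemd, seed=config.seed)
    decompose = erms_approach_A if config.approach == "A" else erms_approach_B
    t1 = time.perf_counter()
    ermsets = [decompose(ds, cfg) for ds in datasets]
    log.info("stage decompose (approach %s): %.1fs", config.approach,
             time.perf_counter() - t1)

    stats: list[ChannelStat] = []
    sources: list[int | None] = [None, *config.modes_of_interest]
    for window in config.windows:
        for mode_index in sources:
            ct, nct, channels = subject_window_amplitudes(ermsets, window, mode_index)
            stats.extend(
                condition_difference_stats(ct, nct, channels, window, mode_index)
            )
    log.info("stage stats: %d channel tests", len(stats))

    pooled: dict[tuple[str, str], np.ndarray] = {}
    for cluster in sorted(set(layout["cluster"])):
        # pool the subject-mean mode series
        per_subj = [
            pool_electrodes(es, layout, cluster, config.pooling_mode)
            for es in ermsets
        ]
        for cond in CONDITIONS:
            pooled[(cluster, cond)] = np.mean([p[cond] for p in per_subj], axis=0)

    topographies: dict[str, pd.DataFrame] = {}
    for window in config.windows:
        for mode_index in sources:
            key = ("ERP" if mode_index is None else f"ERM{mode_index}") \
                + "/" + window.name
            sel = [s for s in stats
                   if s.window == window and s.mode_index == mode_index]
            topographies[key] = topography_values(sel, layout)

    result = PipelineResult(config=config, ermsets=ermsets, stats=stats,
                            pooled=pooled, topographies=topographies)

    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(out / "channel_stats.tsv", result.stats_frame(), config)
        rows = []
        n_s = datasets[0].n_samples
        t_ms = (np.arange(n_s) - datasets[0].onset_index) * 1000.0 \
            / datasets[0].sample_rate
        for (cluster, cond), series in pooled.items():
            for i in range(n_s):
                rows.append((cluster, cond, i, t_ms[i], series[i]))
        _write_table(
            out / "pooled_modes.tsv",
            pd.DataFrame(rows, columns=["cluster", "condition", "sample",
                                        "time_ms", "amplitude"]),
            config,
        )
        for key, topo in topographies.items():
            fname = "topography_" + key.replace("/", "_") + ".tsv"
            _write_table(out / fname, topo, config)
        log.info("outputs written to %s", out)

    log.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return result
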