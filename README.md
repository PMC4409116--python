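# ermkit — event-related modes from EEG

`ermkit` analyses multi-trial, multi-channel event-related EEG with
**ensemble empirical mode decomposition** (EEMD) and the **Hilbert–Huang
transform**, the data-driven alternative to fixed-basis (Fourier/wavelet)
decompositions.  It targets the classic contour-integration paradigm —
detecting a path of aligned Gabor elements (contour, *CT*) hidden among
randomly oriented distractors (non-contour, *NCT*) — and ships generators for
both sides of such a study: the Gabor stimulus displays themselves, and
synthetic EEG with known planted condition effects, so the whole analysis
chain is testable end to end without access to recordings.

## The method

Epochs x(t) of 500 samples at 500 samples/s (−150 → +850 ms around stimulus
onset, 75 pre-stimulus samples) are standardized to zero mean and unit
variance.  EMD represents each signal as

    x(t) = Σ_j c_j(t) + r(t),        c_j(t) = Re{ a_j(t) exp(i φ_j(t)) }

where the intrinsic mode functions (IMFs) c_j are extracted by *sifting* —
repeatedly subtracting the mean of cubic-spline envelopes through the local
extrema — with a fixed iteration count, and r(t) is the non-oscillating
trend.  Decompositions are fixed at 7 IMFs with the trend stored as an 8th
mode.  EEMD repeats EMD over an ensemble of E = 20 copies of the signal
perturbed with white noise of sd 0.2·σ_signal and averages corresponding
modes, suppressing mode mixing.  The Hilbert transform then gives each mode's
instantaneous amplitude a_j(t) and frequency ν_j(t) = (1/2π) dφ_j/dt.

**Event-related modes** (ERMs) come in two flavours: approach **A** decomposes
the per-channel trial-average (the ERP — phase-locked activity only);
approach **B** decomposes every single trial and averages modes per condition
(keeping non-phase-locked activity).  Condition effects are quantified per
channel as the group mean of |amplitude(CT)| − |amplitude(NCT)| averaged
within fixed latency windows around the ERP components (P100 early 60–120 ms
/ late 120–180 ms, N200 early 150–210 ms / late 200–260 ms), tested with a
two-sided paired t-test across subjects (α ∈ {0.05, 0.01, 0.001}, per channel,
uncorrected).  Channels pool into six scalp clusters per hemisphere
(OC, P, PT, CE, FR, AT) for latency comparisons, and per-channel statistics
can be laid out as head topographies with a significance mask.

## Worked example

Simulate six subjects with an early N200 effect planted on posterior channels
(O2, P4, P8) and a late N200 effect on frontal channels (F4, AF4), then run
the full pipeline (approach A, ensemble size 10):

```python
import numpy as np
import ermkit as ek

early = ek.WindowDef("N200", "early", (150.0, 210.0))
late = ek.WindowDef("N200", "late", (200.0, 260.0))
sim = ek.EEGSimConfig(
    n_subjects=6,
    channels=["O1", "O2", "P4", "P8", "C4", "CP4", "F4", "AF4"],
    n_trials_per_condition=60,
    seed=42,
    effect_map=(ek.EffectSpec(("O2", "P4", "P8"), early, -1.2),
                ek.EffectSpec(("F4", "AF4"), late, -1.2)),
)
config = ek.RunConfig(seed=42, approach="A",
                      eemd=ek.EEMDConfig(ensemble_size=10, noise_ratio=0.2, seed=42),
                      windows=(early, late), modes_of_interest=(5,))
result = ek.run_pipeline(config, datasets=ek.synth_eeg_dataset(sim),
                         write_outputs=False)
print(result.stats_frame().round(3))
```

The raw-ERP rows for the planted channels come out as:

```
component phase channel  mean_diff  t_value  p_value tier
     N200 early      O2      1.597   13.890    0.000  ***
     N200 early      P4      0.843    3.852    0.012    *
     N200 early      P8      1.280   17.658    0.000  ***
     N200  late      F4      1.843    9.003    0.000  ***
     N200  late     AF4      1.583    9.655    0.000  ***
```

All five planted channels are detected and no unplanted channel reaches
α = 0.05 in this draw.  `mean_diff` is the group mean of |amp_CT| − |amp_NCT|
in standardized units: positive values mean the contour condition drove the
larger absolute window amplitude.  Pooling mode 5 over the parietal and
frontal clusters shows the planted posterior-to-frontal latency shift of the
N200 trough:

```
pooled ERM5 N200 trough: parietal 176 ms, frontal 234 ms
```

The same pipeline runs from the shell: `ermkit simulate-eeg`,
`ermkit analyze run.yaml`, `ermkit report out/channel_stats.tsv`; Gabor
stimulus displays come from `ermkit simulate-stimuli` (element lists as JSON,
rasters as PGM).

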