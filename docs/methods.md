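# Methods

This note documents the models, numerical choices and known limitations of
`ermkit`: what each stage assumes, which parameters matter, what the
synthetic-data generators do and do not emulate, and therefore what a passing
test suite does and does not demonstrate about real recordings.

## Empirical mode decomposition

Sifting subtracts the mean of the cubic-spline upper and lower envelopes
(through the strict local maxima and minima respectively) from the running
signal.  Design choices:

* **Fixed iteration count** (default 10 per mode, `EEMDConfig.sift_iterations`)
  instead of a formal IMF stopping criterion.  A fixed count makes mode j of
  one signal comparable to mode j of another — a precondition for averaging
  modes across trials and ensemble members.  The count is a configuration
  knob, never hard-coded, and is echoed into output metadata.
* **Mode count fixed at 7 IMFs**, the residual trend appended as the 8th
  stored mode.  Fixing the count in advance (rather than decomposing to
  exhaustion) is again what makes cross-trial mode averaging well defined.
  For 500-sample epochs the extrema usually run out near mode 6–7 anyway;
  when they run out early the remaining mode slots are zero and the trend
  still goes to the last slot, preserving exact additive reconstruction.
* **Extrema**: strict neighbour comparison; a plateau that is a local
  extremum contributes its first sample.  Monotone remainders terminate the
  decomposition.
* **Boundary handling**: before spline fitting, up to two extrema per side
  are mirrored across the endpoints.  Unconstrained splines swing wildly
  beyond the outermost knots, and on 500-sample epochs those end swings
  would contaminate a noticeable fraction of the signal; mirroring is a
  standard, cheap suppression.  No further end correction is applied, so the
  outer few samples of any mode remain the least trustworthy.
* **EEMD**: ensemble of E (default 20) realizations, white Gaussian noise of
  sd `noise_ratio` (default 0.2) times the signal sd, modes averaged across
  the ensemble.  Member n draws from an independent substream derived from
  (seed, n), so results do not depend on evaluation order and members are
  parallelizable by contract.  Averaged modes no longer sum exactly to the
  input: the residual ensemble noise shrinks as noise_ratio·σ/√E (verified
  empirically as an RMS bound of 3·noise_ratio·σ/√E in the tests).
  `noise_ratio=0` reduces EEMD to plain EMD exactly.

## Hilbert spectral analysis

Instantaneous amplitude and phase come from the FFT-based analytic signal;
instantaneous frequency is the centred finite difference of the unwrapped
phase (one-sided at the ends), matching the derivative definition.
Transiently negative frequencies near amplitude nulls are reported, not
clamped.  Because the Hilbert transform has edge artifacts on finite
segments, all summary statistics (mean/median mode frequency, energy checks)
exclude the outer 10% of samples at each end.  The residual trend carries
amplitude only — a trend has no meaningful instantaneous frequency — and its
phase/frequency rows are NaN.  Mode frequencies map onto EEG band names at
the conventional edges (δ < 4 ≤ θ < 8 ≤ α < 13 ≤ β < 30 ≤ γ Hz).

## Gabor stimulus generator

Displays are built on a 10×10 invisible grid whose cell size is
2s/(1+√2) = 1.66 deg for the default inter-element separation s = 2 deg,
giving a 16.6-deg field in which mean distractor spacing matches mean
path-element spacing.  The single-element luminance profile is
L0·(1 + C·sin(k·x·cosθ + k·y·sinθ)·exp(−(x²+y²)/2σ²)) with C = 0.9,
f = 3 cycles/deg, σ = 0.25 deg.  Note the carrier argument is implemented
exactly in this form, which differs from the conventional rotated-coordinate
Gabor (where the carrier depends on x·cosθ + y·sinθ alone); for θ = 0 the two
coincide.

The contour path chains 10 elements: each successive orientation turns by
±α plus a uniform jitter (bound configurable, default ±1°; the turn sign is
drawn per segment), successive centers are 2 ± 0.55 deg apart, no center may
fall in the central 2×2 grid cells (keeping the path off the fixation mark)
and at least 4 must fall in the inner 6×6 (bounding eccentricity).  Whole
paths are redrawn until the constraints hold.  Distractors fill every grid
cell not containing a path-element center, jittered ±0.55 deg per axis with
orientation uniform on [0°, 180°) — orientation is axial, so a wider range
would be redundant.  Non-contour displays are derived from a contour display
by rotating the 10 path elements ±45°, preserving positions and counts.

The overlap rule treats the **visible part** of an element as a disk of
radius 2σ = 0.5 deg (envelope at 13.5% of peak) rasterized at the projector
geometry (600 px over the field ≈ 36 px/deg, configurable): an element is not
drawn if its disk would share more than 5 pixels with the already-drawn
display, with a 200-attempt re-jitter budget per distractor.  A display is
withdrawn and redrawn when more than 10 elements fail or the final count
leaves [90, 100].  The 3σ alternative for the visible radius was ruled out
at design time: at 1.66-deg cell pitch it makes neighbouring distractors
collide so often that the withdrawal rule fires almost always, inconsistent
with the 90–100 element counts the construction is specified to produce.

## Synthetic EEG generator

Each trial is: deterministic ERP components + band oscillations + 1/f noise
+ planted condition effects.

* **Components**: Gaussian bumps (P100 +1.0 at 90/160 ms, N200 −1.2 at
  180/230 ms, P300 +0.8 at 320 ms, N400 −0.6 at 410 ms; widths 45–80 ms,
  Gaussian sd = width/4).  Posterior channels (OC/P/PT clusters) receive the
  early latencies, frontal channels (FR/AT) the late ones, central channels
  (CE) both at half amplitude — emulating the posterior-to-frontal latency
  progression the analysis is meant to resolve.
* **Oscillations**: sinusoids near 25/10/5/2 Hz (β/α/θ/δ; amplitudes
  0.12/0.3/0.35/0.3) with a fresh random phase per trial, shared between the
  j-th trial of each condition so the oscillatory background cancels exactly
  in condition differences.
* **Noise**: 1/f (exponent 1) background, unit-sd shaped in the frequency
  domain, independent per channel and trial, scaled by `noise_sd` = 4.  This
  puts single-trial SNR near 0.25 — components invisible in single trials,
  emerging only after averaging — which is the realistic regime for evoked
  responses.  It also matters statistically: with much weaker noise all
  simulated subjects become near-identical clones and the z-score
  normalization measurably couples a planted effect into every analysis
  window (the effect changes the epoch sd that divides the whole signal),
  producing condition differences at unplanted latencies that no real
  between-subject variability would tolerate.
* **Planted effects**: an effect is a flat-topped tapered-cosine (Tukey,
  α = 0.5) pulse whose support is exactly the stated window, applied as a
  symmetric modulation — +δ/2 to the stated condition, −δ/2 to the other —
  so the window-mean condition difference equals the configured delta
  exactly.  Two shape decisions matter here.  The flat top keeps the pulse
  peak near the window-mean value; a tall narrow bump of equal window mean
  inflates the planted condition's epoch variance enough that z-scoring
  visibly rescales every *other* analysis window on that channel.  The
  symmetric split gives both conditions identical effect variance, removing
  that rescaling asymmetry to first order.  Residual cross-window
  contamination is limited to the 10 ms by which the N200 early (150–210 ms)
  and late (200–260 ms) analysis windows intrinsically overlap.
* **Determinism**: one top-level seed; subject i draws from substream
  (seed, i); datasets are bit-reproducible.

What the generator does **not** emulate: volume conduction (channels are
independent rather than instantaneously mixed), artifacts (blinks, muscle,
line noise) and their removal, trial-to-trial latency jitter of components,
non-stationary oscillation amplitudes, and per-subject morphology
differences beyond what the noise induces.  Passing recovery tests therefore
demonstrates that the statistical machinery detects window-confined
amplitude effects at realistic SNR — not that the pipeline is robust to
artifacts or source mixing.

## Analysis pipeline

* Epochs: 75 pre + 425 post samples; onset at index 75.  z-scoring over the
  whole 500-sample epoch (population sd) subsumes whole-interval baseline
  correction; no separate pre-stimulus baseline is subtracted.  Constant
  epochs are rejected rather than silently zeroed.
* Latency windows are fixed intervals (not per-subject peak-centred;
  peak-centring can be emulated by passing custom `WindowDef`s).  The
  ms→sample mapping is `onset + round-half-up(ms·rate/1000)` with half-open
  `[lo, hi)` ranges, so sample counts are bit-stable across platforms.
* The per-channel statistic is the group mean of |amp_CT| − |amp_NCT|; the
  paired t-test is two-sided; tiers are assigned at α ∈ {0.05, 0.01, 0.001}
  with **no multiple-comparison correction**, matching per-channel reporting
  conventions.  Zero-variance difference vectors (degenerate inputs) yield
  T = 0, p = 1 rather than NaN.
* Approach B shares the EEMD noise substreams across trials by default,
  making it agree with approach A exactly in the identical-trials degenerate
  case; `share_noise=False` gives independent substreams per trial.
* Mode 5 is the default mode of interest for pooling — at this sample rate
  and epoch length it is the mode whose peaks track the slow ERP components
  — but all 8 modes are computed and testable, and the raw-ERP statistics
  are always emitted alongside the per-mode statistics.
* Cluster pooling uses a shipped, editable 62-channel 10-10 layout with
  schematic 2-D positions and a six-cluster assignment per hemisphere
  (OC, P, PT, CE, FR, AT); topography interpolation is inverse-distance
  (power 2) and reproduces channel values at their own positions.

## Problem sizes in the shipped tests

The planted-effect recovery suite runs 6 subjects × 16 channels × 60
trials/condition with an EEMD ensemble of 10 over 10 seeds — sizes at which
the closed-form paired-t power at the planted d = 1.2 comfortably exceeds
the 90% sensitivity bound being checked, while a full suite run stays in the
minutes range.  The statistics calibration uses 1000 null channels and 500
power simulations at n = 18 subjects, where the noncentral-t closed form
gives 98.4% power.  Stimulus constraints are verified over 1000 generated
displays with an independent lattice-counting overlap checker.

## Known limitations

* Plain EMD's exact-reconstruction guarantee does not extend to EEMD output;
  partial reconstructions from averaged modes carry O(σ/√E) ensemble noise.
* Instantaneous frequency of weak modes is noisy near amplitude nulls; use
  the central-80% median for robust summaries.
* The shipped cluster table is schematic: real studies should load their
  cap's measured layout (`load_layout`) rather than rely on the defaults.
* EDF input is not supported; interchange is delimited matrices with JSON
  sidecars.
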