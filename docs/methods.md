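# Methods

This note documents the models, defaults and numerical choices behind
`fearprobe`, and what the synthetic validation does and does not show.

## The paradigm and its data model

One session is 90 cue presentations: 54 CS+ (threat, T) of which
round(0.33·54) = 18 are paired with the aversive US, and 36 CS−
(no-threat, NT). Cues last 5 s and are separated by 5–10 s
inter-stimulus intervals; in TMS mode a pulse is delivered 1000 ms
after every cue onset. US-paired trials are excluded from analysis,
leaving 36 analysable trials per condition. EEG is sampled at 250 Hz.
All amplitudes are microvolts; epoch time axes are milliseconds
relative to cue onset.

## Synthetic recordings

The generator composes, per channel:

* **1/f background** — shared fractional-noise sources (default rank
  `n_channels // 2`) mixed into all channels and scaled to 10 µV SD per
  channel. The limited rank reflects volume conduction (background EEG
  is spatially correlated); it also keeps the ICA problem determined.
  Exponent 1 by default.
* **Evoked components.** Cue-locked components are Hann-windowed
  monophasic deflections (ERP152: 152 ms latency, 60 ms width, 12 µV;
  LPP: 500 ms, 600 ms width, 10 µV baseline amplitude + the condition
  effect, default +12 µV in T — the pattern this paradigm reports).
  TMS-locked components are rendered as a *single phase-continuous
  oscillatory complex*: a PCHIP-interpolated phase hits k·π exactly at
  the k-th configured latency (41/57/81/117/197/317 ms after the
  pulse) and a PCHIP envelope passes through the configured magnitudes
  (16/6/12/12/12/14 µV, alternating polarity). Rationale: successive
  TMS-evoked deflections are half-cycles of one decelerating
  oscillation; rendering them as independent same-sign bumps 16 ms
  apart makes them merge (or shift by ~2 ms) under any 35 Hz low-pass,
  whereas the narrowband complex passes the filter with sub-millisecond
  apex shift for the first component. Component topographies are
  Gaussian patches centred on a scalp region (frontal for ERP152,
  central for LPP, dmPFC for TEPs).
* **Cardiac source** — a spiky QRS-plus-T-wave template repeated at the
  configured rate (±2% beat-to-beat jitter), with condition-dependent
  instantaneous rate inside cue windows (defaults 75 bpm in T, 67 in
  NT, 70 baseline), mixed into all channels through one fixed random
  column at 30 µV. Injected beat times are kept on the recording.
* **50 Hz line noise** (5 µV, common phase, per-channel gain) and a
  **biphasic pulse artifact** (8 ms, 2000 µV) at every TMS time.

ITIs are quantized to the sample grid so cue onsets and pulse times
fall exactly on samples; otherwise epoch-grid rounding alone adds ±2 ms
of latency error to every injected component.

What the simulator does **not** model: realistic forward solutions or
head geometry, spatially structured artifacts (eye movements, muscle),
non-stationary background, or habituation across trials. Passing tests
therefore demonstrate correctness of the *analysis chain* under known
ground truth, not robustness to every property of real recordings.

## Preprocessing

Order: excision → notch → detrend → bad channels → interpolation →
low-pass → epoching. All filters are zero-phase.

* **Excision:** samples in [t−5 ms, t+20 ms] around each pulse (edges
  rounded outward to whole samples) are replaced by a least-squares
  cubic fitted on 40 ms of context per side. An interpolating spline
  chases context noise (violating the artifact-removal bound), and a
  context as short as the gap makes the fit extrapolation-dominated,
  biasing the first post-pulse component's latency by ~0.4 ms —
  both verified against injected truth. A linear-segment mode exists
  for analytical tests.
* **Notch:** IIR notch at 50 Hz (Q = 30), forward-backward.
* **Bad channels:** each channel scored by the median absolute
  deviation of its rectified-signal envelope (100 ms moving average),
  robustly z-scored across channels; default threshold z > 5. This is
  an automated surrogate for the visual inspection such data normally
  receives.
* **Interpolation:** inverse-distance-weighted mean of the 4 nearest
  good channels.
* **Low-pass:** 101-tap linear-phase FIR at 35 Hz, filtfilt. The
  1–30 Hz band-pass variant sometimes used for TMS-EEG data is
  available (`filter_bandpass`); neither is asserted as the single
  truth.
* **Epoching:** [−500, 2000] ms, baseline mean over the half-open
  interval [−500, 0) subtracted per channel and epoch.

## Evoked analysis

* **Peak criterion:** a sample is a peak when 3 contiguous samples
  (12 ms at 250 Hz) on both sides have strictly smaller values
  (positive) or strictly larger values (negative, kept with its sign).
  Plateaus do not qualify. Latency and amplitude are refined by a
  3-point parabolic fit around the apex by default; the reported TEP
  latencies do not lie on a 4 ms sample grid, so sub-sample refinement
  is required to express them at all. Grid mode (`refine=False`) is
  what the brute-force equivalence tests use.
* **Labelling:** ERP152 = first supra-threshold positive peak in
  100–250 ms; LPP = largest positive peak in 300–1000 ms; TEP1…TEP6 =
  up to six successive supra-threshold peaks after the pulse, skipping
  the first 25 ms (the excised-and-interpolated window cannot contain
  evoked extrema, only reconstruction artefacts). The supra-threshold
  level is 3× the robust SD of the evoked pre-cue baseline with a 1 µV
  absolute floor.
* **Sensor choice:** each component is measured at the channel where
  the grand-average (T+NT)/2 waveform is largest inside the component's
  window. The max-|T−NT| alternative is available but follows noise
  for components without a condition effect. A configured
  sensor-of-interest list overrides both.
* **Markers:** per matched labelled component, amplitude(T) −
  amplitude(NT); peak-to-peak measures difference the amplitudes of
  consecutive components in the canonical order 0 → ERP152 → LPP → TMS
  → TEP1 → … → TEP6 (anchors at cue onset and pulse time are waveform
  samples). Across subjects markers are grouped by canonical label;
  table names (e.g. `TEP41-to-TEP57`) use the modal measured latency.
* **SNR:** "mean activity" in the SNR formula is the mean absolute
  amplitude over the window (RMS optional). A signed mean of a
  baseline-corrected window is ≈0 and would explode the ratio; the
  absolute-amplitude reading also naturally yields negative dB when
  evoked activity sits below the baseline level. The signal window must
  be 500 ms long.

## Statistics

* Paired and Welch *t*-tests are computed from their textbook formulas
  (scipy supplies only the t-distribution CDF). Identical inputs give
  t = 0, p = 1; a constant non-zero difference is an error. Default
  sidedness for marker tests is one-sided T > NT, the contrast this
  paradigm tests; two-sided is a flag away.
* Cohen's *d* for paired data defaults to mean difference / SD of
  differences, with the pooled-SD variant available. The two
  definitions differ, and published *d* values for this kind of table
  are not always reproducible from the printed *t* and *n* (t/√n
  deviates from the printed d by a few percent), so the choice stays
  configurable rather than resolved.
* **FDR:** Benjamini–Hochberg step-up with monotonicity enforcement,
  cross-checked against statsmodels on random vectors.
* **Cluster permutation:** per-channel one-sample *t* on subject
  difference maps; channels with two-sided p < 0.05 form
  graph-connected clusters (neighbour graph: channels within 1.5× the
  10th percentile of pairwise distances), positive and negative
  separately; cluster mass = sum of member *t*; the null records the
  maximum |mass| over sign-flipped replicates, and
  p = (1+#{null ≥ |mass|})/(1+n_perm). The permutation loop is
  vectorized (sign flips leave x² invariant, so channel variances
  follow from the flipped means), which is why 200 null datasets ×
  500 permutations run in seconds.
* **Backward elimination:** all 8 volume predictors enter when
  n > k+1 (otherwise a univariate p < 0.2 pre-screen), the worst
  predictor above the 10% level is dropped iteratively, and the final
  model is summarized by r², adjusted r² and its *F*-test. Note an
  inherent property of the procedure: with 7 noise candidates at
  α_remove = 0.10, the final model retains a chance survivor in
  roughly half of replicates; the true predictor itself is retained
  essentially always (100/100 in the validation).

## ICA heart rate

Extended infomax (natural gradient with sub/super-Gaussian switching
from the kurtosis sign) on PCA-whitened data, components capped at the
numerical rank (interpolated channels make the covariance singular).
Optimization is two-phase: stochastic block passes for fast initial
separation, then deterministic full-batch natural-gradient polishing so
the 1e-7 weight-delta tolerance is met at a true stationary point; the
learning rate starts at the dimension-scaled 0.01/log(n²), anneals by
0.9 on oscillation (>60°) during the stochastic phase, and adapts
(grow 1.05 / shrink 0.7) during polishing, with divergence restarts at
half the rate.

Cardiac rows are identified by (a) periodicity — an autocorrelation
peak above 0.3 inside the 40–140 bpm lag band, computed on the 120 ms
energy envelope because a beat-jittered spike train decorrelates at
one-period lag while its envelope does not — and (b) spikiness, excess
kurtosis above 3 (at 120 bpm the QRS duty cycle halves kurtosis to
~4.6, so a threshold of 5 would reject genuine cardiac components; the
periodicity gate keeps single-spike artefacts out). Beat detection is
QRS-band (5–30 Hz) energy peak-picking with a 250 ms refractory
period, an adaptive threshold, a search-back pass for attenuated beats
in over-long gaps, and polarity invariance. Before detection the known
50 ms concatenation taper is divided out so beats near segment joins
are not lost, and the condition's time-locked average is subtracted
before ICA so the evoked response cannot masquerade as a periodic
source. The rate is 60·(n_beats−1)/(t_last−t_first); across injected
rates of 55–120 bpm from 180 s concatenations the recovered rate is
within 2 bpm.

## Problem sizes and determinism

Desk-scale defaults: 64 channels for the library default, 16–32
channels and 2–20 subjects in the validation suite, 500–1000
permutations, full 90-trial schedules everywhere. Every random stage
takes an explicit seed; cohort runs derive independent child seeds per
subject via `SeedSequence`, and identical configurations reproduce
reports exactly (asserted in tests).

## Known limitations

* Latency recovery through the full chain is accurate to ~0.4 ms for
  the first TEP and ~2–3 ms for later, broader components; overlap of
  neighbouring opposite-polarity deflections under the 35 Hz filter is
  the dominant residual distortion.
* The LPP's flat 600 ms top makes its apex latency ill-defined to tens
  of milliseconds under noise; its amplitude marker is unaffected.
* The cardiac template is stylized (no morphology variation, no
  HRV beyond 2% jitter), and artifact identification thresholds were
  chosen to separate the shipped fixtures with margin — real data may
  need retuning.
* The regression stage inherits backward elimination's optimism: r² of
  selected models at n = 20 with 8 candidates is inflated by
  selection; the overall F-test p-values are reported as-is and then
  FDR-adjusted across markers.
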