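# Methods

This note documents the models, defaults and design choices behind
`adsleep`, and what the synthetic-data experiments do and do not show.

## Sleep-state scoring model

Epochs are 30 s. Evidence is computed per channel and combined by the
median across channels ("across frontocentral channels" without
privileging any single electrode). The decision hierarchy is:

1. **SWS** — the 0.5–4 Hz zero-phase band-limited signal is segmented
   into half-waves at zero crossings; a half-wave is scoreable delta when
   its peak-to-peak excursion with an adjacent half-wave exceeds 75 µV.
   If scoreable delta covers ≥ 20 % of the epoch (inclusive — "at least
   20 %"), the epoch is SWS.
2. **Alpha-delta sleep** — an SWS epoch whose 8–14 Hz activity is
   *persistent*: the fraction of 1-s subwindows in which alpha-band
   variance exceeds 15 % of broadband (0.5–30 Hz) variance is ≥ 0.6.
   Alpha-delta is carried as a subtype of SWS, so every alpha-delta epoch
   also satisfies the SWS criteria. The persistence fraction is this
   package's operationalization of a "constant" overlay; no standard
   quantitative definition exists.
3. **Wake-alpha guard** — a non-SWS epoch with persistent alpha
   (persistence ≥ 0.6) is resting eyes-closed wake. This check runs
   before the stage-2 marker check because a continuous alpha rhythm
   bleeds into the 9–16 Hz envelope detector and can mimic burst
   activity; genuine stage-2 spindle persistence is ~0.1, far below the
   threshold, so the guard cannot mask stage 2.
4. **Stage 2** — spindle bursts (intervals ≥ 0.5 s where the smoothed
   9–16 Hz analytic envelope exceeds 3× its epoch median) and/or
   K-complexes (biphasic <2 Hz transients exceeding 100 µV peak-to-peak)
   with a median count ≥ 1.
5. Otherwise wake (configurable to `unscored`).

Thresholds not fixed by the scoring convention (envelope multiplier 3,
persistence floor 0.6, alpha/broadband ratio 0.15, K-complex amplitude
100 µV) were calibrated once against the synthetic generator and frozen;
all are exposed in `StagingThresholds`.

## Spectral estimation and normalization

* **Multitaper PSD.** DPSS tapers with time–bandwidth NW = 3 and K = 5
  tapers on 30-s epochs (resolution bandwidth 2·NW/T = 0.2 Hz),
  eigenvalue-unweighted mean over tapers, mean over epochs. One-sided
  density scaled so that ∑ PSD·Δf equals the mean per-epoch variance
  (Parseval). Taper parameters are conventional for sleep EEG and
  config-exposed.
* **Power-law (1/f) normalization.** `a·fᵇ` is fitted by OLS on
  (log f, log P) over peak-free ranges — 5–6 & 17–18 Hz for stage 2,
  4–6 & 23–24 Hz for SWS — and subtracted on the **linear** power scale.
  The residual keeps its sign; negative values are retained when
  integrating (flooring at zero would bias band power upward).
  Subtraction-then-integration is only well defined on one consistent
  scale; dB values are a presentation-layer transform
  (`BandPower.db()`), not part of the computation.
* **Band power.** Residual integrated over half-open bands [lo, hi) —
  spindle 9–16, delta 0.5–4, alpha 8–14 Hz — with the Riemann rule
  Δf·∑residual (exactly additive over disjoint sub-bands; a trapezoid
  alternative is available). Half-open bins prevent shared band edges
  (e.g. 8–14 and 9–16) from being counted twice.
* **Dominant spindle frequency.** The largest strict local maximum of
  the residual in 9–16 Hz; a quadratic is fitted within ±1 Hz and its
  vertex (clipped to the range) is the reported frequency. A peak counts
  as *present* only if its height is positive, ≥ 5 % of the maximum
  residual in range, and ≥ 1.5× the fitted background at that frequency.
  The last floor is what makes "no spindle peak → no value" operational:
  for a peak-free residual the 5 % rule alone would always fire on
  noise. The 1.5× level was calibrated once against generator ground
  truth (genuine peaks ≥ 2.8×, cross-channel Laplacian leakage ≤ 0.93×,
  noise ≤ 0.33×) and frozen.

## Hjorth Laplacian montage

Each channel is re-referenced to the mean of its nearest neighbours;
channels with fewer than two present neighbours are dropped with a
warning. For full 10–20 montages a standard nearest-neighbour map is
used (e.g. C3 ↔ {F3, P3, T7, Cz}); recordings containing only the six
frontocentral analysis channels (F3, F4, FC5, FC6, C3, C4) fall back to
a within-hemisphere map (C3 ↔ {F3, FC5}, etc.). Both maps are
user-overridable; no neighbour normalization varies at edge electrodes.

## Statistics

Features are analysed at the (time point × channel) level with
hemisphere derived from electrode-index parity. Channel-level values are
treated as replicates — the convention of the longitudinal single-patient
analyses this package serves — which is pseudo-replication in the strict
sense and is documented as a caveat wherever the report is consumed.

* Two-way fixed-effects ANOVA (condition × hemisphere) per variable,
  Type II sums of squares by default (robust for unbalanced crossed
  designs without interaction emphasis; Types I/III switchable), via
  statsmodels OLS. Factors with one observed level, or interactions made
  inestimable by empty cells, are dropped with warnings.
* One-way ANOVA across the active-condition time points.
* Tukey HSD on the studentized-range distribution with the Tukey–Kramer
  harmonic-mean correction for unequal group sizes, using the one-way
  residual mean square; with two groups this reduces exactly to the
  pooled t-test (q = √2·|t|).
* Missing spindle-frequency cells are dropped listwise, never imputed.
  A condition in which fewer than half the channels report a spindle
  peak is excluded from the spindle-frequency analysis entirely,
  mirroring the removal of a post-treatment visit whose spindle peak
  survives in one channel only.

## Synthetic polysomnography generator

The generator replaces human-scored patient EEG. Morphology is chosen
for **spectral** realism — only spectral features are consumed
downstream — not waveform fidelity:

* background: Gaussian 1/f^β noise (β = 1.5, scale 30 µV²/Hz at 1 Hz);
  each rfft bin carries the exact band integral of the power law, so the
  epoch variance equals the analytic PSD integral in expectation;
* spindles: Gaussian-windowed sinusoids (~1 s, 35 µV p-p, 6/min);
* K-complexes: biphasic derivative-of-Gaussian transients (~1 s,
  150 µV p-p);
* delta: trains of frequency-jittered, edge-tapered sinusoids
  (0.5–2 Hz region, >75 µV p-p) placed without overlap until a target
  coverage fraction is reached;
* alpha-delta overlay: a full-epoch sinusoid with a slow (0.2 Hz)
  raised-cosine amplitude modulation (±12.5 %), "constant" at the 30-s
  scale yet non-stationary;
* sampling rate 250 Hz (clinical convention; the acquisition rate of the
  source recordings is not public).

Event times, phases and noise are drawn **independently per channel**
from child streams of the epoch seed. This sacrifices the cross-channel
coherence of real EEG events in exchange for statistically independent
channel-level observations, which is what makes the channel-as-replicate
ANOVA calibration test meaningful. Hemispheric asymmetry is a
per-channel gain (`channel_gains`); the post-treatment loss of spindles
in all channels but C3 is a per-channel gain on the spindle component
only (`spindle_channel_gains`).

The default longitudinal study (`default_study_config`) encodes the
treatment trajectory as per-time-point overrides: spindle frequency
9.8 → 10.5/11.0/10.6 Hz under active treatment and 11.7 Hz (C3 only,
reduced amplitude) after withdrawal; SWS delta coverage/amplitude rising
under treatment (0.22/110 µV → up to 0.45/150 µV) and partially
regressing; a 70 µV p-p alpha overlay on SWS before treatment, absent
during, re-emerging at 80 µV p-p and 10 Hz after withdrawal; a left
stage-2 gain of 1.08 reproducing the left>right spindle-power asymmetry.
Five time points map to conditions pre (1), active (3), post (1), with
32 epochs per state per time point (the 30–35 epoch convention).

**What passing tests show — and don't.** Recovery of injected
parameters, nominal type-I error, and reproduction of the encoded effect
pattern validate the *estimators and statistics*, under Gaussian
backgrounds, stationary states, and independent channels. They do not
establish performance on real patient EEG, which has coherent
cross-channel events, artifacts beyond amplitude outliers, non-1/f
backgrounds, and drifting states within epochs.

## Numerical and problem-size choices

* Staging recall is validated on a balanced 4 × 25-epoch fixture;
  scorer accuracy on the default study is ~98 %.
* The spindle-frequency sweep uses 9.5–13.5 Hz in 0.5 Hz steps,
  16 epochs per step; recovery error is < 0.05 Hz, asserted against the
  0.2 Hz resolution bandwidth.
* The null-model type-I-error experiment runs 200 replicates of a
  reduced pipeline (5 time points × 4 stage-2 epochs at 125 Hz →
  spindle-power ANOVA); measured 3.5–7.5 % across seeds at α = 0.05.
* EDF output is 16-bit with per-channel physical scaling; round-trip
  error is bounded by one quantization step plus header rounding
  (~0.02 µV). The writer requires an integer sampling rate.
* Epoch extraction uses the half-open nighttime window [20:00, 06:00)
  on annotation onsets, earliest-first, overlaps resolved in favour of
  the earlier epoch. Artifact rejection: |amplitude| > 500 µV or
  channel peak-to-peak < 0.5 µV.

## Known limitations

* Not a general AASM auto-scorer: no N1/REM discrimination, no
  EOG/EMG, no arousal scoring.
* Single-subject longitudinal designs: the ANOVA treats channels as
  replicates; inferences are about this recording series, not a
  population.
* The alpha-delta persistence criterion is this package's formalization;
  other operationalizations of "constant" alpha would shift the
  SWS/alpha-delta boundary.
* No time-frequency analysis, individual spindle event detection in the
  time domain, or connectivity measures.
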