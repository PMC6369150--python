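# adsleep

Quantification of longitudinal sleep-EEG biomarkers in clinical
neurophysiology, with a focus on the signatures that track recovery in the
severely injured brain: stage-2 sleep spindles, slow wave sleep (SWS)
delta activity, and **alpha-delta sleep** — the abnormal intrusion of a
continuous 8–14 Hz rhythm onto high-voltage slow waves.

The package is aimed at researchers who need to compare sleep spectra
across visits separated by months or years, where absolute EEG power is
not comparable between recordings and only normalized spectral features
are meaningful.

## What it computes

For each visit and sleep state, from 30-s scored epochs:

1. **Hjorth Laplacian montage** — each channel referenced to the mean of
   its nearest neighbours, rejecting common-mode signal.
2. **Multitaper PSD** — DPSS tapers (default NW = 3, K = 5 on 30-s
   epochs), eigenvalue-unweighted taper mean, averaged over epochs;
   one-sided, Parseval-normalized, in µV²/Hz.
3. **Power-law normalization** — a background `P̂(f) = a·fᵇ` is fitted by
   least squares in log–log coordinates over peak-free ranges (5–6 and
   17–18 Hz for stage 2; 4–6 and 23–24 Hz for SWS) and subtracted, so
   arbitrary between-visit differences in broadband power cancel.
4. **Band features of the residual** — spindle power (9–16 Hz), delta
   power (0.5–4 Hz), alpha power (8–14 Hz), and the dominant spindle
   frequency as the vertex of a quadratic fitted around the largest
   residual peak in the spindle range ("no value" when no peak exists).
5. **Statistics** — a long-format table (time point × channel × variable,
   hemisphere derived from the 10–20 label) analysed with condition ×
   hemisphere fixed-effects ANOVAs (Type II), a one-way ANOVA within the
   active-treatment time points, and Tukey HSD post-hocs at α = 0.05.

Sleep states are assigned by rule: SWS when >75 µV delta (<4 Hz)
half-waves cover ≥20 % of the epoch (inclusive); alpha-delta sleep as an
SWS subtype when a near-continuous 8–14 Hz overlay rides on it; stage 2
by K-complexes and/or 9–16 Hz spindle bursts; wake otherwise.

A seeded synthetic polysomnography generator (`adsleep.synthetic`)
renders all four states with known ground truth — spindle bursts,
K-complexes, polymorphic delta trains and continuous alpha overlays on a
1/f^β background — and a full longitudinal study (pre / active / post
condition trajectory) for end-to-end validation.

## Worked example

```python
from adsleep import spec_for_state, generate_epoch, classify_epoch
from adsleep.recording import Epoch
from adsleep.spectral import (multitaper_psd, fit_power_law,
                              normalize_spectrum, integrate_band,
                              find_spindle_peak)

# score one synthetic alpha-delta epoch
rec, truth = generate_epoch(spec_for_state("alpha_delta", seed=1))
ep = Epoch(rec.samples, rec.fs_hz, rec.labels)
label = classify_epoch(ep)
print(f"state={label.state}  delta_fraction={label.evidence.delta_fraction:.2f}  "
      f"alpha_persistence={label.evidence.alpha_persistence:.2f}")

# spindle features from 30 stage-2 epochs with a true 10.9 Hz spindle
epochs = []
for seed in range(30):
    rec, _ = generate_epoch(spec_for_state("stage2", seed=seed,
                                           spindle_freq_hz=10.9))
    epochs.append(Epoch(rec.samples, rec.fs_hz, rec.labels))
est = multitaper_psd(epochs, nw=3, k=5)
ns = normalize_spectrum(est, fit_power_law(est, [(5, 6), (17, 18)]))
power = integrate_band(ns, (9, 16))
peak = find_spindle_peak(ns)[ns.labels.index("C3")]
print(f"C3 spindle power = {power.value('C3'):.1f} uV^2,  "
      f"dominant spindle frequency = {peak.freq_hz:.2f} Hz")
```

prints

```
state=alpha_delta  delta_fraction=0.41  alpha_persistence=0.95
C3 spindle power = 6.5 uV^2,  dominant spindle frequency = 10.89 Hz
```

The epoch is scored as alpha-delta sleep because scoreable delta waves
cover 41 % of it (≥ 20 %) *and* the alpha overlay persists through 95 %
of its 1-s subwindows; the normalized stage-2 spectrum recovers the true
10.9 Hz dominant spindle frequency to 0.01 Hz.

The same pipeline runs end to end from the command line:

```bash
adsleep run-all --out run/ --seed 0        # simulate → stage → … → analyze
adsleep stage --in run/TP1.csv.gz --out annot.csv
```

`run/report.json` then contains, per variable, the ANOVA table, Tukey
comparisons, the within-active analysis, and staging accuracy against
ground truth; `run/manifest.json` records the configuration hash and
seed. Re-running with the same seed reproduces the report byte for byte.

## Layout

| module | role |
| --- | --- |
| `adsleep.synthetic` | seeded epoch/study generator with ground-truth log |
| `adsleep.io` | EDF and gzipped-CSV I/O, Laplacian montage, epoch extraction, artifact rejection |
| `adsleep.spectral` | multitaper PSD, power-law normalization, band power, spindle peak |
| `adsleep.staging` | rule-based wake / stage-2 / SWS / alpha-delta scoring |
| `adsleep.stats` | study table, ANOVAs, Tukey HSD, full report |
| `adsleep.pipeline`, `adsleep.cli`, `adsleep.config` | orchestration, YAML config, `adsleep` CLI |
| `adsleep.validation` | recall / recovery / type-I-error experiments |

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
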