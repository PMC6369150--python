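"""Self-validation experiments on synthetic ground truth.

Each function runs a scaled, seeded experiment through the real analysis
path and returns the measured quantity, so that recovery performance can
be quoted from computation rather than assumption:

* :func:`staging_recall` — per-class recall of the rule-based scorer on a
  balanced wake/stage2/sws/alpha-delta dataset at default amplitudes;
* :func:`spindle_frequency_sweep` — recovered dominant spindle frequency
  versus truth across the spindle band;
* :func:`null_condition_rejection_rate` — empirical type-I error of the
  feature → ANOVA pipeline when no condition effect exists;
* :func:`condition_effect_detection_rate` — detection power as a function
  of the injected alpha-power effect size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recording import Epoch
from .spectral import (
    find_spindle_peak,
    fit_power_law,
    integrate_band,
    multitaper_psd,
    normalize_spectrum,
)
from .staging import StagingThresholds, classify_epoch
from .stats import anova_two_way, build_study_table
from .synthetic import DEFAULT_CHANNELS, DEFAULT_CONDITION_MAP, generate_epoch, spec_for_state

__all__ = [
    "staging_recall",
    "spindle_frequency_sweep",
    "null_condition_rejection_rate",
    "condition_effect_detection_rate",
]

STAGE2_FIT_RANGES = ((5.0, 6.0), (17.0, 18.0))
SWS_FIT_RANGES = ((4.0, 6.0), (23.0, 24.0))


def _epoch(rec) -> Epoch:
    return Epoch(rec.samples, rec.fs_hz, list(rec.labels))


def staging_recall(
    n_per_class: int = 25,
    seed: int = 0,
    thresholds: StagingThresholds = StagingThresholds(),
    fs_hz: float = 250.0,
) -> dict[str, float]:
    """Per-class recall on a balanced dataset at default generator amplitudes."""
    states = ("wake", "stage2", "sws", "alpha_delta")
    seeds = np.random.SeedSequence(seed).generate_state(len(states) * n_per_class)
    recall: dict[str, float] = {}
    k = 0
    for state in states:
        hits = 0
        for _ in range(n_per_class):
            rec, truth = generate_epoch(
                spec_for_state(state, seed=int(seeds[k]) % 2**31), fs_hz=fs_hz
            )
            k += 1
            if classify_epoch(_epoch(rec), thresholds).state == truth.state:
                hits += 1
        recall[state] = hits / n_per_class
    return recall


def spindle_frequency_sweep(
    freqs_hz: np.ndarray | None = None,
    n_epochs: int = 16,
    seed: int = 0,
    fs_hz: float = 250.0,
) -> pd.DataFrame:
    """Recovered dominant spindle frequency per true frequency.

    For each true frequency, ``n_epochs`` stage-2 epochs are generated,
    multitaper-averaged, power-law-normalized and peak-fitted; the
    estimate is the median vertex across channels.
    """
    if freqs_hz is None:
        freqs_hz = np.arange(9.5, 13.51, 0.5)
    rows = []
    ss = np.random.SeedSequence(seed).generate_state(len(freqs_hz) * n_epochs)
    k = 0
    for f0 in freqs_hz:
        epochs = []
        for _ in range(n_epochs):
            rec, _ = generate_epoch(
                spec_for_state("stage2", seed=int(ss[k]) % 2**31, spindle_freq_hz=float(f0)),
                fs_hz=fs_hz,
            )
            k += 1
            epochs.append(_epoch(rec))
        est = multitaper_psd(epochs, nw=3, k=5)
        ns = normalize_spectrum(est, fit_power_law(est, STAGE2_FIT_RANGES))
        peaks = find_spindle_peak(ns)
        found = [p.freq_hz for p in peaks if p.present]
        rows.append(
            dict(
                true_hz=float(f0),
                est_hz=float(np.median(found)) if found else np.nan,
                n_channels_present=len(found),
            )
        )
    return pd.DataFrame(rows)


def _band_power_table(
    tp_specs: dict[str, dict],
    state: str,
    band: tuple[float, float],
    variable: str,
    n_epochs: int,
    fs_hz: float,
    seed: int,
    fit_ranges,
) -> pd.DataFrame:
    """Per-(time point, channel) band power from freshly generated epochs."""
    rows = []
    tps = list(tp_specs)
    ss = np.random.SeedSequence(seed).generate_state(len(tps) * n_epochs)
    k = 0
    for tp in tps:
        epochs = []
        overrides = dict(tp_specs[tp])
        st = overrides.pop("state", state)  # a slot may render as another state
        for _ in range(n_epochs):
            rec, _ = generate_epoch(
                spec_for_state(st, seed=int(ss[k]) % 2**31, **overrides),
                channels=DEFAULT_CHANNELS,
                fs_hz=fs_hz,
            )
            k += 1
            epochs.append(_epoch(rec))
        est = multitaper_psd(epochs, nw=3, k=5)
        ns = normalize_spectrum(est, fit_power_law(est, fit_ranges))
        bp = integrate_band(ns, band)
        for ch, val in zip(bp.labels, bp.values):
            rows.append(dict(time_point=tp, channel=ch, variable=variable, value=float(val)))
    return pd.DataFrame(rows)


def null_condition_rejection_rate(
    n_reps: int = 200,
    seed: int = 0,
    n_epochs_per_tp: int = 4,
    fs_hz: float = 125.0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the feature → ANOVA pipeline.

    Every time point is generated from the identical stage-2 spec (no
    condition effect); the rate at which the condition main effect of the
    spindle-power ANOVA is significant estimates the pipeline's type-I
    error, which should match the nominal ``alpha``.
    """
    tp_specs = {tp: {} for tp in DEFAULT_CONDITION_MAP}
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    hits = 0
    for r in range(n_reps):
        features = _band_power_table(
            tp_specs,
            "stage2",
            (9.0, 16.0),
            "spindle_power",
            n_epochs_per_tp,
            fs_hz,
            int(rep_seeds[r]) % 2**31,
            STAGE2_FIT_RANGES,
        )
        table = build_study_table(features, DEFAULT_CONDITION_MAP)
        res = anova_two_way(table, "spindle_power")
        if res.effects["condition"].p < alpha:
            hits += 1
    return hits / n_reps


def condition_effect_detection_rate(
    effect_alpha_amp_uv: float,
    n_reps: int = 20,
    seed: int = 0,
    n_epochs_per_tp: int = 4,
    fs_hz: float = 125.0,
    alpha: float = 0.05,
) -> float:
    """Power to detect a condition effect on SWS alpha power.

    Off-stimulation time points carry a continuous alpha overlay of the
    given peak-to-peak amplitude on top of SWS; on-stimulation time points
    carry none.  Amplitude 0 reduces to the null design.
    """
    base = dict(delta_amp_uv=130.0, delta_coverage=0.3)
    if effect_alpha_amp_uv > 0:
        off = dict(
            base,
            state="alpha_delta",
            alpha_amp_uv=float(effect_alpha_amp_uv),
            alpha_continuous=True,
        )
    else:
        off = dict(base)
    tp_specs = {
        tp: (off if cond in ("pre", "post") else dict(base))
        for tp, cond in DEFAULT_CONDITION_MAP.items()
    }
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    hits = 0
    for r in range(n_reps):
        features = _band_power_table(
            tp_specs,
            "sws",
            (8.0, 14.0),
            "alpha_power",
            n_epochs_per_tp,
            fs_hz,
            int(rep_seeds[r]) % 2**31,
            SWS_FIT_RANGES,
        )
        table = build_study_table(features, DEFAULT_CONDITION_MAP)
        res = anova_two_way(table, "alpha_power")
        if res.effects["condition"].p < alpha:
            hits += 1
    return hits / n_reps
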