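"""Rule-based sleep-state scoring of 30-s epochs.

Implements the scoring scheme used for longitudinal sleep comparison in
severely brain-injured patients:

* **SWS** — large polymorphic delta (<4 Hz) waves exceeding 75 µV
  peak-to-peak covering at least 20% of the epoch ("at least 20%" is
  inclusive: a fraction of exactly 0.20 scores SWS);
* **alpha-delta sleep** — SWS criteria met *plus* a near-continuous
  8-14 Hz oscillation riding on the slow waves (scored as a subtype of
  SWS, so every alpha-delta epoch also satisfies the SWS rule);
* **stage 2** — K-complexes and/or 9-16 Hz spindle bursts across the
  frontocentral channels, without meeting the SWS delta rule;
* **wake** (or ``unscored``) otherwise.

Evidence is computed per channel and combined by the median across
channels (the multi-channel "across frontocentral channels" rule).  Every
numeric threshold that the scoring convention leaves to the human scorer
(envelope multiplier, persistence floor, K-complex amplitude) is an
explicit configurable default, calibrated once against the synthetic
generator and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .recording import Annotation, Epoch

__all__ = [
    "StagingThresholds",
    "Evidence",
    "EpochLabel",
    "delta_fraction",
    "detect_stage2_markers",
    "alpha_persistence",
    "classify_epoch",
    "stage_recording",
]


@dataclass(frozen=True)
class StagingThresholds:
    """All tunable constants of the rule-based scorer."""

    delta_fraction_min: float = 0.20  # inclusive ("at least 20%")
    delta_amp_uv: float = 75.0
    delta_freq_hi_hz: float = 4.0
    spindle_env_multiplier: float = 3.0
    spindle_min_dur_s: float = 0.5
    kcomplex_amp_uv: float = 100.0
    alpha_persistence_min: float = 0.6
    alpha_ratio_floor: float = 0.15
    default_state: str = "wake"  # label when nothing matches: "wake" or "unscored"


@dataclass
class Evidence:
    delta_fraction: float
    spindle_event_count: float
    kcomplex_count: float
    alpha_persistence: float


@dataclass
class EpochLabel:
    """Sleep-state assignment plus the evidence it rests on."""

    state: str  # wake | stage2 | sws | alpha_delta | unscored
    evidence: Evidence

    @property
    def is_sws_like(self) -> bool:
        """Alpha-delta sleep is scored under the SWS category."""
        return self.state in ("sws", "alpha_delta")


@lru_cache(maxsize=64)
def _sos(fs: float, lo: float | None, hi: float | None, order: int = 4):
    nyq = fs / 2.0
    if lo is not None and hi is not None:
        return butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    if hi is not None:
        return butter(order, hi / nyq, btype="lowpass", output="sos")
    raise ValueError("need at least a high cutoff")


def _bandpass(x: np.ndarray, fs: float, lo: float | None, hi: float) -> np.ndarray:
    return sosfiltfilt(_sos(fs, lo, hi), x)


# ---------------------------------------------------------------------------
# Evidence operations
# ---------------------------------------------------------------------------

def _halfwave_flags(xf: np.ndarray, amp_uv: float) -> np.ndarray:
    """Mark samples belonging to half-waves whose adjacent-extrema
    peak-to-peak exceeds ``amp_uv``."""
    sign = np.signbit(xf)
    bounds = np.flatnonzero(np.diff(sign)) + 1
    edges = np.concatenate(([0], bounds, [len(xf)]))
    n_seg = len(edges) - 1
    if n_seg < 2:
        return np.zeros(len(xf), bool)
    ext = np.array(
        [
            xf[edges[i] : edges[i + 1]].max()
            if not sign[edges[i]]
            else xf[edges[i] : edges[i + 1]].min()
            for i in range(n_seg)
        ]
    )
    pp = np.abs(np.diff(ext))  # p-p between consecutive half-waves
    flags = np.zeros(len(xf), bool)
    for i in range(n_seg):
        big_prev = i > 0 and pp[i - 1] > amp_uv
        big_next = i < n_seg - 1 and pp[i] > amp_uv
        if big_prev or big_next:
            flags[edges[i] : edges[i + 1]] = True
    return flags


def delta_fraction(
    epoch: Epoch, amp_uv_threshold: float = 75.0, freq_hi_hz: float = 4.0
) -> float:
    """Fraction of the epoch occupied by scoreable delta waves.

    The signal is band-limited to 0.5-``freq_hi_hz`` Hz (zero-phase); a
    half-wave counts as a delta wave when its peak-to-peak amplitude with
    an adjacent half-wave exceeds ``amp_uv_threshold``.  Returns the
    median across channels.  Monotone non-increasing in the threshold.
    """
    fracs = []
    for row in epoch.samples:
        xf = _bandpass(row, epoch.fs_hz, 0.5, freq_hi_hz)
        fracs.append(_halfwave_flags(xf, amp_uv_threshold).mean())
    return float(np.median(fracs))


def detect_stage2_markers(
    epoch: Epoch, thresholds: StagingThresholds = StagingThresholds()
) -> tuple[float, float]:
    """Median spindle-burst and K-complex counts across channels.

    Spindle events are intervals of at least ``spindle_min_dur_s`` where
    the smoothed 9-16 Hz analytic envelope exceeds
    ``spindle_env_multiplier`` times its epoch median.  K-complexes are
    isolated biphasic transients in the <2 Hz band whose adjacent-extrema
    peak-to-peak exceeds ``kcomplex_amp_uv``.
    """
    if epoch.fs_hz < 64:
        raise ValueError("marker detection requires fs >= 64 Hz")
    fs = epoch.fs_hz
    min_len = int(round(thresholds.spindle_min_dur_s * fs))
    smooth = max(1, int(round(0.1 * fs)))
    kernel = np.ones(smooth) / smooth
    spindle_counts, kc_counts = [], []
    for row in epoch.samples:
        band = _bandpass(row, fs, 9.0, 16.0)
        env = np.convolve(np.abs(hilbert(band)), kernel, mode="same")
        thr = thresholds.spindle_env_multiplier * np.median(env)
        above = env > thr
        spindle_counts.append(_count_runs(above, min_len))

        slow = _bandpass(row, fs, None, 2.0)
        flags = _halfwave_flags(slow, thresholds.kcomplex_amp_uv)
        kc_counts.append(_count_runs(flags, min_len))
    return float(np.median(spindle_counts)), float(np.median(kc_counts))


def _count_runs(mask: np.ndarray, min_len: int) -> int:
    padded = np.concatenate(([False], mask, [False]))
    rise = np.flatnonzero(np.diff(padded.astype(np.int8)) == 1)
    fall = np.flatnonzero(np.diff(padded.astype(np.int8)) == -1)
    return int(np.sum((fall - rise) >= min_len))


def alpha_persistence(
    epoch: Epoch,
    alpha_band: tuple[float, float] = (8.0, 14.0),
    broad_band: tuple[float, float] = (0.5, 30.0),
    ratio_floor: float = 0.15,
    win_s: float = 1.0,
) -> float:
    """Fraction of 1-s subwindows with sustained alpha-range power.

    A subwindow counts when its alpha-band (8-14 Hz) variance exceeds
    ``ratio_floor`` of its broadband (0.5-30 Hz) variance.  Median across
    channels.  This operationalizes the "constant" alpha overlay of
    alpha-delta sleep as a persistence fraction.
    """
    if epoch.fs_hz < 64:
        raise ValueError("alpha persistence requires fs >= 64 Hz")
    fs = epoch.fs_hz
    w = int(round(win_s * fs))
    n_win = epoch.samples.shape[1] // w
    if n_win == 0:
        raise ValueError("epoch shorter than one subwindow")
    fracs = []
    for row in epoch.samples:
        a = _bandpass(row, fs, *alpha_band)[: n_win * w].reshape(n_win, w)
        b = _bandpass(row, fs, *broad_band)[: n_win * w].reshape(n_win, w)
        ratio = a.var(axis=1) / np.maximum(b.var(axis=1), 1e-12)
        fracs.append((ratio > ratio_floor).mean())
    return float(np.median(fracs))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_epoch(
    epoch: Epoch, thresholds: StagingThresholds = StagingThresholds()
) -> EpochLabel:
    """Assign a sleep state by the rule hierarchy.

    1. Delta fraction >= 20% (inclusive) → SWS; additionally persistent
       alpha → alpha-delta sleep (an SWS subtype).
    2. Otherwise, a persistent continuous alpha rhythm without scoreable
       delta is the resting (eyes-closed) wake signature → wake.
    3. Otherwise, spindle bursts or K-complexes present → stage 2.
    4. Otherwise wake (or ``unscored``, per configuration).

    The wake-alpha guard precedes the marker check because a continuous
    8-14 Hz rhythm can spill into the 9-16 Hz spindle band and mimic
    burst activity; genuine stage-2 spindles are transient (persistence
    well below the threshold), so the guard cannot shadow them.
    """
    dfrac = delta_fraction(
        epoch, thresholds.delta_amp_uv, thresholds.delta_freq_hi_hz
    )
    spindles, kcs = detect_stage2_markers(epoch, thresholds)
    pers = alpha_persistence(epoch, ratio_floor=thresholds.alpha_ratio_floor)
    ev = Evidence(
        delta_fraction=dfrac,
        spindle_event_count=spindles,
        kcomplex_count=kcs,
        alpha_persistence=pers,
    )
    if dfrac >= thresholds.delta_fraction_min:
        state = "alpha_delta" if pers >= thresholds.alpha_persistence_min else "sws"
    elif pers >= thresholds.alpha_persistence_min:
        state = thresholds.default_state
    elif spindles >= 1 or kcs >= 1:
        state = "stage2"
    else:
        state = thresholds.default_state
    return EpochLabel(state=state, evidence=ev)


def stage_recording(
    rec,
    epoch_s: float = 30.0,
    thresholds: StagingThresholds = StagingThresholds(),
) -> list[Annotation]:
    """Score a recording in consecutive ``epoch_s`` windows.

    Returns one annotation per full window, tagged with the assigned
    state — the annotation stream consumed by epoch extraction.
    """
    n_ep = int(rec.n_times // int(round(epoch_s * rec.fs_hz)))
    w = int(round(epoch_s * rec.fs_hz))
    out = []
    for i in range(n_ep):
        ep = Epoch(
            samples=rec.samples[:, i * w : (i + 1) * w],
            fs_hz=rec.fs_hz,
            labels=list(rec.labels),
            onset_s=i * epoch_s,
        )
        label = classify_epoch(ep, thresholds)
        out.append(Annotation(onset_s=i * epoch_s, duration_s=epoch_s, tag=label.state))
    return out
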