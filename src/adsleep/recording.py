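"""Core containers for multi-channel scalp EEG.

A :class:`Recording` is a channel-by-time array in microvolts with 10-20
channel labels, a sampling rate, an optional wall-clock start time and a
list of annotations.  A :class:`Epoch` is a fixed-duration (30 s by
default) slice of a recording used as the unit of sleep scoring and
spectral estimation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Annotation", "Recording", "Epoch", "hemisphere_of", "LEFT_CHANNELS", "RIGHT_CHANNELS"]

#: Frontocentral analysis channels split by hemisphere (odd index = left).
LEFT_CHANNELS = ("F3", "FC5", "C3")
RIGHT_CHANNELS = ("F4", "FC6", "C4")


def hemisphere_of(label: str) -> str:
    """Return ``"left"``/``"right"`` for a 10-20 label, by electrode index parity.

    Odd-numbered electrodes sit over the left hemisphere, even-numbered over
    the right; midline ("z") labels raise ``ValueError``.
    """
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise ValueError(f"midline or malformed channel label {label!r} has no hemisphere")
    return "left" if int(digits) % 2 == 1 else "right"


@dataclass(frozen=True)
class Annotation:
    """A tagged interval: onset and duration in seconds from recording start."""

    onset_s: float
    duration_s: float
    tag: str

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    """Multi-channel EEG time series in microvolts.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_times)``, in µV.
    fs_hz
        Sampling rate in Hz.
    labels
        Unique channel names (canonical upper-case 10-20 labels).
    start_time
        Wall-clock time of the first sample; used by the nighttime
        (8 p.m.-6 a.m.) window filter.  Optional.
    annotations
        Tagged intervals (sleep-state epochs, events, artifacts).
    """

    samples: np.ndarray
    fs_hz: float
    labels: list[str]
    start_time: _dt.datetime | None = None
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_times) array")
        self.labels = [str(l).upper() for l in self.labels]
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channel rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the sample row for one channel label."""
        try:
            idx = self.labels.index(label.upper())
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording {self.labels}") from None
        return self.samples[idx]

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        rows = [self.labels.index(l.upper()) for l in labels]
        return Recording(
            samples=self.samples[rows].copy(),
            fs_hz=self.fs_hz,
            labels=[self.labels[i] for i in rows],
            start_time=self.start_time,
            annotations=list(self.annotations),
        )


@dataclass
class Epoch:
    """A fixed-length scoring segment (30 s by convention) in µV."""

    samples: np.ndarray
    fs_hz: float
    labels: list[str]
    onset_s: float = 0.0
    source: str = ""
    label: object | None = None  # an EpochLabel once scored

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be (n_channels, n_times)")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("label count does not match channel rows")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_hz

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def channel(self, label: str) -> np.ndarray:
        idx = [l.upper() for l in self.labels].index(label.upper())
        return self.samples[idx]
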