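"""Reading, writing and conditioning of EEG recordings.

Formats
-------
* EDF (16-bit European Data Format): read through :mod:`mne`; written by a
  minimal self-contained writer (physical dimension µV, one-second data
  records).
* CSV, optionally gzipped: first column ``time_s``, one column per channel,
  header row of channel labels.
* Annotations: CSV with columns ``onset_s, duration_s, tag``.

Conditioning
------------
:func:`hjorth_laplacian` applies a nearest-neighbour surface Laplacian
(each channel minus the mean of its neighbours), the standard spatial
sharpening / common-mode rejection step for scalp sleep EEG.
:func:`extract_epochs` pulls non-overlapping 30-s scoring epochs whose
onsets fall in the nighttime clock window, and :func:`reject_artifacts`
drops gross-artifact epochs by amplitude and flatline thresholds.
"""

from __future__ import annotations

import datetime as _dt
import gzip
import struct
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .recording import Annotation, Epoch, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "hjorth_laplacian",
    "extract_epochs",
    "reject_artifacts",
    "default_neighbor_map",
    "NEIGHBOR_MAP_1020",
    "NEIGHBOR_MAP_6CH",
    "NIGHT_WINDOW",
]

#: Default nighttime scoring window: onsets in [20:00, 06:00), half-open.
NIGHT_WINDOW = (_dt.time(20, 0), _dt.time(6, 0))

#: Nearest-neighbour ("small") Laplacian for the 10-20 montage, with the
#: FC5/FC6 extension used by the frontocentral analysis set.
NEIGHBOR_MAP_1020: dict[str, tuple[str, ...]] = {
    "FP1": ("FP2", "F7", "F3", "FZ"),
    "FP2": ("FP1", "F8", "F4", "FZ"),
    "F7": ("FP1", "F3", "T7"),
    "F3": ("FP1", "F7", "FZ", "C3"),
    "FZ": ("FP1", "FP2", "F3", "F4", "CZ"),
    "F4": ("FP2", "F8", "FZ", "C4"),
    "F8": ("FP2", "F4", "T8"),
    "FC5": ("F7", "F3", "T7", "C3"),
    "FC6": ("F8", "F4", "T8", "C4"),
    "T7": ("F7", "C3", "P7"),
    "C3": ("F3", "T7", "CZ", "P3"),
    "CZ": ("FZ", "C3", "C4", "PZ"),
    "C4": ("F4", "T8", "CZ", "P4"),
    "T8": ("F8", "C4", "P8"),
    "P7": ("T7", "P3", "O1"),
    "P3": ("C3", "P7", "PZ", "O1"),
    "PZ": ("CZ", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "P8", "PZ", "O2"),
    "P8": ("T8", "P4", "O2"),
    "O1": ("P7", "P3", "PZ", "O2"),
    "O2": ("P8", "P4", "PZ", "O1"),
}

#: Within-hemisphere fallback map for recordings containing only the six
#: frontocentral analysis channels, where 10-20 nearest neighbours are
#: unavailable.
NEIGHBOR_MAP_6CH: dict[str, tuple[str, ...]] = {
    "F3": ("FC5", "C3"),
    "FC5": ("F3", "C3"),
    "C3": ("F3", "FC5"),
    "F4": ("FC6", "C4"),
    "FC6": ("F4", "C4"),
    "C4": ("F4", "FC6"),
}


def default_neighbor_map(labels: Iterable[str]) -> Mapping[str, tuple[str, ...]]:
    """Choose a neighbour map for the given channel set.

    Uses the full 10-20 nearest-neighbour map when the recording carries
    more than the six analysis channels, else the within-hemisphere
    six-channel map.
    """
    labels = {l.upper() for l in labels}
    if labels <= set(NEIGHBOR_MAP_6CH):
        return NEIGHBOR_MAP_6CH
    return NEIGHBOR_MAP_1020


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_csv(rec: Recording, path: Path) -> None:
    t = np.arange(rec.n_times) / rec.fs_hz
    df = pd.DataFrame({"time_s": t})
    for i, lab in enumerate(rec.labels):
        df[lab] = rec.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")


def _read_csv(path: Path) -> Recording:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline().strip()
    fields = first.split(",")
    if all(_is_number(f) for f in fields):
        raise ValueError(f"{path}: first row is numeric; expected a header of channel labels")
    if fields[0].lower() not in {"time_s", "time", "t"}:
        raise ValueError(f"{path}: first column must be time in seconds, got {fields[0]!r}")
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer sampling rate")
    fs = 1.0 / np.median(np.diff(t))
    samples = df.iloc[:, 1:].to_numpy(float).T
    return Recording(samples=samples, fs_hz=float(round(fs, 6)), labels=list(df.columns[1:]))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# EDF (16-bit), µV physical dimension
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_records = int(np.ceil(rec.n_times / fs))
    start = rec.start_time or _dt.datetime(2000, 1, 1, 0, 0, 0)

    data = rec.samples
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_edf_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_edf_field(256 * (ns + 1), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))  # record duration, s
        fh.write(_edf_field(ns, 4))
        for lab in rec.labels:
            fh.write(_edf_field(f"EEG {lab}", 16))
        for _ in range(ns):
            fh.write(_edf_field("", 80))
        for _ in range(ns):
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(f"{v:.2f}"[:8], 8))
        for v in pmax:
            fh.write(_edf_field(f"{v:.2f}"[:8], 8))
        for _ in range(ns):
            fh.write(_edf_field(_EDF_DIG_MIN, 8))
        for _ in range(ns):
            fh.write(_edf_field(_EDF_DIG_MAX, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 80))
        for _ in range(ns):
            fh.write(_edf_field(fs, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 32))

        # re-read the physical extrema exactly as written, so that the
        # digital scaling is consistent with the truncated header text
        pmin_w = np.array([float(f"{v:.2f}"[:8]) for v in pmin])
        pmax_w = np.array([float(f"{v:.2f}"[:8]) for v in pmax])
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax_w - pmin_w)

        padded = np.zeros((ns, n_records * fs))
        padded[:, : rec.n_times] = data
        for r in range(n_records):
            block = padded[:, r * fs : (r + 1) * fs]
            dig = np.round((block - pmin_w[:, None]) * scale[:, None]) + _EDF_DIG_MIN
            dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    labels = [lab.removeprefix("EEG ").strip().upper() for lab in raw.ch_names]
    meas = raw.info.get("meas_date")
    start = None
    if meas is not None:
        start = meas.replace(tzinfo=None) if isinstance(meas, _dt.datetime) else None
    annotations = [
        Annotation(float(on), float(du), str(tag))
        for on, du, tag in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return Recording(
        samples=data_uv,
        fs_hz=float(raw.info["sfreq"]),
        labels=labels,
        start_time=start,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Public read/write
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = str(path).lower()
    if name.endswith(".edf"):
        return "edf"
    if name.endswith(".csv") or name.endswith(".csv.gz"):
        return "csv"
    raise ValueError(f"cannot infer format of {path}; pass format='edf' or 'csv'")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or (gzipped) CSV; samples in µV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as EDF or (gzipped) CSV, returning the path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "tag"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    return [
        Annotation(float(r.onset_s), float(r.duration_s), str(r.tag))
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(a.onset_s, a.duration_s, a.tag) for a in annotations],
        columns=["onset_s", "duration_s", "tag"],
    )
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Hjorth Laplacian montage
# ---------------------------------------------------------------------------

def hjorth_laplacian(
    rec: Recording,
    nmap: Mapping[str, Sequence[str]] | None = None,
    min_neighbors: int = 2,
) -> Recording:
    """Apply a Hjorth (nearest-neighbour) Laplacian montage.

    Each channel is replaced by its own signal minus the mean of its
    neighbours that are present in the recording.  Channels with fewer
    than ``min_neighbors`` present neighbours are dropped (reported via
    a warning).  The operation is linear in the input samples.
    """
    if nmap is None:
        nmap = default_neighbor_map(rec.labels)
    nmap = {k.upper(): tuple(n.upper() for n in v) for k, v in nmap.items()}
    for key, neighbors in nmap.items():
        if key in neighbors:
            raise ValueError(f"channel {key} listed as its own neighbour")

    kept_labels: list[str] = []
    rows: list[np.ndarray] = []
    dropped: list[str] = []
    present = set(rec.labels)
    for lab in rec.labels:
        neighbors = [n for n in nmap.get(lab, ()) if n in present]
        if len(neighbors) < min_neighbors:
            dropped.append(lab)
            continue
        ref = np.mean([rec.channel(n) for n in neighbors], axis=0)
        rows.append(rec.channel(lab) - ref)
        kept_labels.append(lab)
    if not kept_labels:
        raise ValueError("Laplacian montage empty: no channel has enough neighbours")
    if dropped:
        warnings.warn(
            f"Laplacian dropped channels lacking >= {min_neighbors} neighbours: {dropped}",
            stacklevel=2,
        )
    return Recording(
        samples=np.vstack(rows),
        fs_hz=rec.fs_hz,
        labels=kept_labels,
        start_time=rec.start_time,
        annotations=list(rec.annotations),
    )


# ---------------------------------------------------------------------------
# Epoch extraction and artifact rejection
# ---------------------------------------------------------------------------

def _in_clock_window(t: _dt.time, window: tuple[_dt.time, _dt.time]) -> bool:
    """Half-open clock-interval membership, wrapping past midnight."""
    lo, hi = window
    if lo <= hi:
        return lo <= t < hi
    return t >= lo or t < hi


def extract_epochs(
    rec: Recording,
    state_tag: str,
    window: tuple[_dt.time, _dt.time] | None = NIGHT_WINDOW,
    n: int | None = None,
    epoch_s: float = 30.0,
) -> list[Epoch]:
    """Extract up to ``n`` non-overlapping epochs tagged ``state_tag``.

    An annotation qualifies when its onset clock time lies in the half-open
    nighttime ``window`` (ignored when the recording has no start time or
    ``window`` is None).  Overlaps are resolved earliest-first; epochs that
    would run past the end of the recording are skipped.  If fewer than
    ``n`` qualify, all are returned with a warning.
    """
    matches = sorted(
        (a for a in rec.annotations if a.tag == state_tag), key=lambda a: a.onset_s
    )
    if window is not None and rec.start_time is not None:
        matches = [
            a
            for a in matches
            if _in_clock_window(
                (rec.start_time + _dt.timedelta(seconds=a.onset_s)).time(), window
            )
        ]
    n_samp = int(round(epoch_s * rec.fs_hz))
    epochs: list[Epoch] = []
    last_end = -np.inf
    for a in matches:
        if a.onset_s < last_end:  # overlap: keep the earlier epoch
            continue
        i0 = int(round(a.onset_s * rec.fs_hz))
        if i0 + n_samp > rec.n_times:
            continue
        epochs.append(
            Epoch(
                samples=rec.samples[:, i0 : i0 + n_samp].copy(),
                fs_hz=rec.fs_hz,
                labels=list(rec.labels),
                onset_s=a.onset_s,
                source=state_tag,
            )
        )
        last_end = a.onset_s + epoch_s
        if n is not None and len(epochs) == n:
            break
    if not epochs:
        raise ValueError(f"no epochs tagged {state_tag!r} inside the scoring window")
    if n is not None and len(epochs) < n:
        warnings.warn(
            f"requested {n} epochs tagged {state_tag!r} but only {len(epochs)} available",
            stacklevel=2,
        )
    return epochs


def reject_artifacts(
    epochs: Sequence[Epoch],
    amp_limit_uv: float = 500.0,
    flat_limit_uv: float = 0.5,
) -> tuple[list[Epoch], list[tuple[Epoch, str]]]:
    """Split epochs into (kept, rejected-with-reason).

    An epoch is rejected with reason ``"amplitude"`` if any channel sample
    exceeds ±``amp_limit_uv``, or ``"flat"`` if any channel's peak-to-peak
    over the whole epoch is below ``flat_limit_uv``.
    """
    if amp_limit_uv <= 0 or flat_limit_uv <= 0:
        raise ValueError("artifact limits must be positive")
    kept: list[Epoch] = []
    rejected: list[tuple[Epoch, str]] = []
    for ep in epochs:
        if np.any(np.abs(ep.samples) > amp_limit_uv):
            rejected.append((ep, "amplitude"))
        elif np.any(ep.samples.max(axis=1) - ep.samples.min(axis=1) < flat_limit_uv):
            rejected.append((ep, "flat"))
        else:
            kept.append(ep)
    return kept, rejected
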