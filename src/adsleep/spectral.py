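"""Multitaper spectra, power-law normalization and spectral features.

The quantitative core of the pipeline:

* :func:`multitaper_psd` — DPSS (discrete prolate spheroidal sequence)
  multitaper PSD, eigenvalue-unweighted mean across tapers, averaged
  across epochs, one-sided and Parseval-normalized (µV²/Hz).
* :func:`fit_power_law` — least-squares fit of ``a * f**b`` in log-log
  coordinates over peak-free frequency ranges.
* :func:`normalize_spectrum` — subtraction of the fitted power-law
  background from the calculated spectrum, removing arbitrary
  between-visit differences in broadband power so that oscillatory peaks
  can be compared longitudinally.
* :func:`integrate_band` — band power of the residual over half-open
  frequency bands.
* :func:`find_spindle_peak` — dominant spindle frequency as the vertex of
  a quadratic fitted around the largest residual peak in the 9-16 Hz
  range; absence of a peak is a valid result ("no value recorded").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import dpss as _dpss

from .recording import Epoch

__all__ = [
    "SpectralEstimate",
    "PowerLawFit",
    "NormalizedSpectrum",
    "BandPower",
    "SpindlePeak",
    "multitaper_psd",
    "fit_power_law",
    "normalize_spectrum",
    "integrate_band",
    "find_spindle_peak",
]


@dataclass
class SpectralEstimate:
    """Per-channel one-sided PSD on a uniform frequency grid (µV²/Hz)."""

    freqs_hz: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    labels: list[str]
    n_epochs: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.psd = np.atleast_2d(np.asarray(self.psd, float))
        if self.psd.shape != (len(self.labels), len(self.freqs_hz)):
            raise ValueError("psd shape must be (n_channels, n_freqs)")
        df = np.diff(self.freqs_hz)
        if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6):
            raise ValueError("frequency grid must be strictly increasing and uniform")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class PowerLawFit:
    """Per-channel power-law background ``a * f**b`` fitted in log-log space."""

    coeff_a: np.ndarray  # (n_channels,)
    exponent_b: np.ndarray
    fit_ranges_hz: tuple[tuple[float, float], ...]
    residual_rms: np.ndarray  # RMS of log10-power residuals inside fit ranges
    labels: list[str]
    freqs_hz: np.ndarray  # grid the fit was computed on

    def predict(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Fitted background on ``freqs_hz`` (one row per channel); f=0 maps to 0."""
        f = np.asarray(freqs_hz, float)
        out = np.zeros((len(self.labels), len(f)))
        pos = f > 0
        out[:, pos] = self.coeff_a[:, None] * f[pos] ** self.exponent_b[:, None]
        return out


@dataclass
class NormalizedSpectrum:
    """Residual spectrum (calculated minus fitted background), sign preserved."""

    freqs_hz: np.ndarray
    residual: np.ndarray  # (n_channels, n_freqs)
    fit: PowerLawFit
    labels: list[str]

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class BandPower:
    """Integrated residual over a half-open band [lo, hi), per channel."""

    band_hz: tuple[float, float]
    values: np.ndarray  # (n_channels,), unit·Hz on the linear scale
    labels: list[str]

    def value(self, channel: str) -> float:
        return float(self.values[self.labels.index(channel.upper())])

    def db(self) -> np.ndarray:
        """Presentation-layer dB transform (10·log10 of positive values)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 10.0 * np.log10(self.values)


@dataclass
class SpindlePeak:
    """Dominant spindle peak for one channel; absent peaks carry no frequency."""

    channel: str
    present: bool
    freq_hz: float | None = None
    height: float | None = None


# ---------------------------------------------------------------------------
# Multitaper estimation
# ---------------------------------------------------------------------------

def multitaper_psd(
    epochs: Sequence[Epoch],
    nw: float = 3.0,
    k: int | None = None,
    fs_hz: float | None = None,
) -> SpectralEstimate:
    """Average DPSS multitaper PSD across epochs.

    Parameters
    ----------
    epochs
        Same-length, same-rate epochs (one state at one visit).
    nw
        Time-bandwidth product; the resolution half-bandwidth is ``nw / T``
        Hz for epoch length ``T`` seconds.
    k
        Number of tapers; defaults to ``2*nw - 1`` and must not exceed it.
    fs_hz
        Override for the sampling rate (defaults to the epochs' rate).
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    if k is None:
        k = int(2 * nw - 1)
    if k > 2 * nw - 1 + 1e-9:
        raise ValueError(f"k={k} exceeds 2*NW-1={2 * nw - 1}")
    n = epochs[0].samples.shape[1]
    fs = float(fs_hz or epochs[0].fs_hz)
    labels = list(epochs[0].labels)
    for ep in epochs:
        if ep.samples.shape[1] != n or ep.fs_hz != epochs[0].fs_hz:
            raise ValueError("all epochs must share length and sampling rate")

    tapers = _dpss(n, nw, Kmax=k)  # (k, n), unit energy
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    one_sided = np.full(len(freqs), 2.0)
    one_sided[0] = 1.0
    if n % 2 == 0:
        one_sided[-1] = 1.0

    acc = np.zeros((len(labels), len(freqs)))
    for ep in epochs:
        # (k, n_ch, n_freq): taper each channel, mean power across tapers
        spec = np.fft.rfft(tapers[:, None, :] * ep.samples[None, :, :], axis=-1)
        acc += (np.abs(spec) ** 2).mean(axis=0)
    psd = acc / len(epochs) * one_sided / fs
    return SpectralEstimate(
        freqs_hz=freqs,
        psd=psd,
        labels=labels,
        n_epochs=len(epochs),
        params=dict(nw=nw, k=k, fs_hz=fs, n_samples=n, epoch_s=n / fs),
    )


# ---------------------------------------------------------------------------
# Power-law background and normalization
# ---------------------------------------------------------------------------

def _range_mask(freqs: np.ndarray, ranges: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(freqs), bool)
    for lo, hi in ranges:
        sel = (freqs >= lo) & (freqs <= hi)
        if sel.sum() < 2:
            raise ValueError(f"fit range ({lo}, {hi}) Hz contains fewer than 2 bins")
        mask |= sel
    return mask


def fit_power_law(
    spec: SpectralEstimate, fit_ranges_hz: Sequence[tuple[float, float]]
) -> PowerLawFit:
    """Fit ``a * f**b`` per channel over the union of peak-free ranges.

    Ordinary least squares on (log f, log P); the fit ranges are chosen to
    exclude the oscillatory bands of interest so the fit captures only the
    broadband background shape.
    """
    ranges = tuple((float(lo), float(hi)) for lo, hi in fit_ranges_hz)
    mask = _range_mask(spec.freqs_hz, ranges)
    f = spec.freqs_hz[mask]
    if np.any(f <= 0):
        raise ValueError("fit ranges must not include 0 Hz")
    P = spec.psd[:, mask]
    if np.any(P <= 0):
        raise ValueError("non-positive power inside fit ranges; is this a residual spectrum?")
    lf = np.log(f)
    lP = np.log(P)
    design = np.column_stack([np.ones_like(lf), lf])
    coef, *_ = np.linalg.lstsq(design, lP.T, rcond=None)
    intercept, slope = coef
    log10_resid = (lP - (intercept[:, None] + slope[:, None] * lf)) / np.log(10.0)
    return PowerLawFit(
        coeff_a=np.exp(intercept),
        exponent_b=slope,
        fit_ranges_hz=ranges,
        residual_rms=np.sqrt((log10_resid**2).mean(axis=1)),
        labels=list(spec.labels),
        freqs_hz=spec.freqs_hz.copy(),
    )


def normalize_spectrum(spec: SpectralEstimate, fit: PowerLawFit) -> NormalizedSpectrum:
    """Subtract the fitted power-law background from the calculated spectrum.

    The residual keeps its sign (it is noise-like around zero away from
    oscillatory peaks).  The DC bin, where a power law is undefined, is
    dropped from the residual grid.
    """
    if len(fit.freqs_hz) != len(spec.freqs_hz) or not np.allclose(
        fit.freqs_hz, spec.freqs_hz
    ):
        raise ValueError("fit was computed on a different frequency grid")
    pos = spec.freqs_hz > 0
    freqs = spec.freqs_hz[pos]
    residual = spec.psd[:, pos] - fit.predict(freqs)
    return NormalizedSpectrum(
        freqs_hz=freqs, residual=residual, fit=fit, labels=list(spec.labels)
    )


def integrate_band(
    ns: NormalizedSpectrum, band_hz: tuple[float, float], method: str = "sum"
) -> BandPower:
    """Integrate the residual over the half-open band ``[lo, hi)``.

    ``method="sum"`` (default) is the Riemann rule ``Δf · Σ residual``,
    which is exactly additive over disjoint sub-bands; ``"trapezoid"`` is
    available as an alternative quadrature.
    """
    lo, hi = float(band_hz[0]), float(band_hz[1])
    if hi <= lo:
        raise ValueError("band must satisfy lo < hi")
    f = ns.freqs_hz
    if lo < f[0] - ns.df_hz or hi > f[-1] + ns.df_hz:
        raise ValueError(f"band ({lo}, {hi}) Hz outside spectral grid [{f[0]}, {f[-1]}]")
    sel = (f >= lo) & (f < hi)
    if not np.any(sel):
        raise ValueError(f"band ({lo}, {hi}) Hz contains no frequency bins")
    if method == "sum":
        values = ns.residual[:, sel].sum(axis=1) * ns.df_hz
    elif method == "trapezoid":
        values = np.trapezoid(ns.residual[:, sel], dx=ns.df_hz, axis=1)
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return BandPower(band_hz=(lo, hi), values=values, labels=list(ns.labels))


# ---------------------------------------------------------------------------
# Dominant spindle frequency
# ---------------------------------------------------------------------------

def find_spindle_peak(
    ns: NormalizedSpectrum,
    search_hz: tuple[float, float] = (9.0, 16.0),
    fit_halfwidth_hz: float = 1.0,
    prominence_frac: float = 0.05,
    rel_background_floor: float = 1.5,
) -> list[SpindlePeak]:
    """Dominant spindle peak per channel within ``search_hz``.

    The largest strict local maximum of the residual inside the range is
    located and a quadratic is fitted to the residual within
    ``±fit_halfwidth_hz``; the vertex frequency (clipped to the range) is
    the dominant spindle frequency.  A peak counts as present only if its
    height is positive, exceeds ``prominence_frac`` of the maximum residual
    in the range, and exceeds ``rel_background_floor`` times the fitted
    power-law background at the peak — otherwise no value is recorded.
    """
    lo, hi = search_hz
    f = ns.freqs_hz
    sel = np.flatnonzero((f >= lo) & (f <= hi))
    if sel.size < 3:
        raise ValueError("search range contains too few bins")
    background = ns.fit.predict(f)
    out: list[SpindlePeak] = []
    for ci, ch in enumerate(ns.labels):
        r = ns.residual[ci]
        # strict local maxima with both neighbours on the full grid
        cand = [
            i
            for i in sel
            if 0 < i < len(f) - 1 and r[i] > r[i - 1] and r[i] > r[i + 1]
        ]
        if not cand:
            out.append(SpindlePeak(channel=ch, present=False))
            continue
        floor = prominence_frac * r[sel].max()
        cand = [i for i in cand if r[i] > 0 and r[i] >= floor]
        cand = [i for i in cand if r[i] >= rel_background_floor * background[ci, i]]
        if not cand:
            out.append(SpindlePeak(channel=ch, present=False))
            continue
        ipk = max(cand, key=lambda i: r[i])
        near = np.flatnonzero(np.abs(f - f[ipk]) <= fit_halfwidth_hz)
        vertex = f[ipk]
        if near.size >= 3:
            c2, c1, _ = np.polyfit(f[near], r[near], 2)
            if c2 < 0:
                vertex = float(np.clip(-c1 / (2 * c2), lo, hi))
        out.append(
            SpindlePeak(channel=ch, present=True, freq_hz=float(vertex), height=float(r[ipk]))
        )
    return out
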