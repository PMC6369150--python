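"""Spectral estimation, power-law normalization, band power, peak finding."""

import numpy as np
import pytest

from adsleep.recording import Epoch
from adsleep.spectral import (
    NormalizedSpectrum,
    SpectralEstimate,
    find_spindle_peak,
    fit_power_law,
    integrate_band,
    multitaper_psd,
    normalize_spectrum,
)
from tests.conftest import as_epoch, white_noise_epochs


def _flat_estimate(freqs, psd_rows, labels=None):
    labels = labels or [f"CH{i}" for i in range(np.atleast_2d(psd_rows).shape[0])]
    return SpectralEstimate(freqs, psd_rows, labels, n_epochs=1)


# ---------------------------------------------------------------------------
# multitaper
# ---------------------------------------------------------------------------

def test_parseval_on_white_noise():
    eps = white_noise_epochs(32, n=2000, fs=100.0, seed=1)
    est = multitaper_psd(eps, nw=3, k=5)
    total = est.psd[0].sum() * est.df_hz
    mean_var = np.mean([ep.samples.var() for ep in eps])
    assert total == pytest.approx(mean_var, rel=0.05)
    # flat at the fs-appropriate density (two-sided variance 1 over fs)
    inner = est.psd[0][(est.freqs_hz > 5) & (est.freqs_hz < 45)]
    assert inner.mean() == pytest.approx(2.0 / 100.0, rel=0.05)


def test_sinusoid_power_concentrates_at_frequency():
    fs, T, A, f0 = 250.0, 30.0, 4.0, 11.0
    t = np.arange(int(fs * T)) / fs
    ep = Epoch((A * np.sin(2 * np.pi * f0 * t))[None, :], fs, ["C3"])
    est = multitaper_psd([ep], nw=3, k=5)
    total = est.psd[0].sum() * est.df_hz
    assert total == pytest.approx(A**2 / 2, rel=0.05)
    half_bw = 3.0 / T
    near = (est.freqs_hz >= f0 - 2 * half_bw) & (est.freqs_hz <= f0 + 2 * half_bw)
    assert est.psd[0][near].sum() * est.df_hz == pytest.approx(A**2 / 2, rel=0.05)


def test_multitaper_matches_averaged_periodogram_oracle():
    """Independent oracle: mean level of the boxcar periodogram averaged
    over 200 white-noise epochs equals the multitaper mean level within 2%."""
    eps = white_noise_epochs(200, n=1000, fs=100.0, seed=7)
    est = multitaper_psd(eps, nw=3, k=5)
    pgrams = []
    for ep in eps:
        x = ep.samples[0]
        X = np.fft.rfft(x)
        p = (np.abs(X) ** 2) / (len(x) * 100.0)
        p[1:-1] *= 2.0
        pgrams.append(p)
    oracle = np.mean(pgrams, axis=0)
    sel = (est.freqs_hz > 2) & (est.freqs_hz < 48)
    assert est.psd[0][sel].mean() == pytest.approx(oracle[sel].mean(), rel=0.02)


def test_multitaper_input_validation():
    eps = white_noise_epochs(2, n=1000)
    with pytest.raises(ValueError, match="at least one"):
        multitaper_psd([])
    with pytest.raises(ValueError, match="exceeds"):
        multitaper_psd(eps, nw=2, k=9)
    bad = white_noise_epochs(1, n=500)
    with pytest.raises(ValueError, match="share length"):
        multitaper_psd(eps + bad)


# ---------------------------------------------------------------------------
# power-law fit / normalization
# ---------------------------------------------------------------------------

def test_power_law_exact_recovery():
    freqs = np.arange(0.5, 40.0, 0.1)
    est = _flat_estimate(freqs, 10.0 * freqs ** (-2.0))
    fit = fit_power_law(est, [(4, 6), (20, 24)])
    assert fit.coeff_a[0] == pytest.approx(10.0, rel=1e-12)
    assert fit.exponent_b[0] == pytest.approx(-2.0, abs=1e-12)
    assert fit.residual_rms[0] == pytest.approx(0.0, abs=1e-12)

    flat = _flat_estimate(freqs, np.full_like(freqs, 3.0))
    assert fit_power_law(flat, [(4, 6), (20, 24)]).exponent_b[0] == pytest.approx(0.0, abs=1e-12)


def test_power_law_recovered_from_synthetic_background():
    from adsleep.synthetic import EpochSpec, generate_epoch

    eps = []
    for seed in range(32):
        rec, _ = generate_epoch(EpochSpec(state="wake", seed=seed, background_exponent=1.5))
        eps.append(as_epoch(rec))
    est = multitaper_psd(eps, nw=3, k=5)
    fit = fit_power_law(est, [(4, 6), (23, 24)])
    assert np.mean(fit.exponent_b) == pytest.approx(-1.5, abs=0.2)


def test_fit_errors():
    freqs = np.arange(0.5, 40.0, 0.1)
    est = _flat_estimate(freqs, 10.0 * freqs ** (-2.0))
    with pytest.raises(ValueError, match="fewer than 2 bins"):
        fit_power_law(est, [(50, 51)])
    res = _flat_estimate(freqs, np.full_like(freqs, 1.0))
    res.psd[0, 40] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        fit_power_law(res, [(4, 6)])


def _bump(freqs, center, height, width=0.5):
    return height * np.exp(-0.5 * ((freqs - center) / width) ** 2)


def test_normalization_residual_zero_on_pure_power_law():
    freqs = np.arange(0.5, 40.0, 0.05)
    est = _flat_estimate(freqs, 8.0 * freqs ** (-1.3))
    ns = normalize_spectrum(est, fit_power_law(est, [(5, 6), (17, 18)]))
    assert np.allclose(ns.residual, 0.0, atol=1e-10)


def test_normalization_isolates_injected_bump():
    freqs = np.arange(0.5, 40.0, 0.05)
    height = 5.0
    psd = 8.0 * freqs ** (-1.3) + _bump(freqs, 11.0, height)
    est = _flat_estimate(freqs, psd)
    ns = normalize_spectrum(est, fit_power_law(est, [(5, 6), (17, 18)]))
    on = np.abs(ns.freqs_hz - 11.0) < 1.0
    off = (np.abs(ns.freqs_hz - 11.0) > 4.0)
    assert ns.residual[0][on].max() == pytest.approx(height, rel=0.05)
    assert np.abs(ns.residual[0][off]).max() < 0.05 * height


def test_background_rescaling_leaves_bump_band_power_invariant():
    """The stated purpose of the normalization: arbitrary background scale
    differences between visits must not move the residual band power."""
    freqs = np.arange(0.5, 40.0, 0.05)
    bump = _bump(freqs, 11.0, 5.0)
    vals = []
    for c in (1.0, 3.7):
        est = _flat_estimate(freqs, c * 8.0 * freqs ** (-1.3) + bump)
        ns = normalize_spectrum(est, fit_power_law(est, [(5, 6), (17, 18)]))
        vals.append(integrate_band(ns, (9, 16)).values[0])
    assert vals[1] == pytest.approx(vals[0], rel=0.10)


def test_normalization_idempotent_in_fit_ranges():
    """After subtraction, no power-law trend remains in the fit ranges."""
    from scipy.stats import linregress

    freqs = np.arange(0.5, 40.0, 0.05)
    est = _flat_estimate(freqs, 8.0 * freqs ** (-1.3) + _bump(freqs, 11.0, 5.0))
    fit = fit_power_law(est, [(5, 6), (17, 18)])
    ns = normalize_spectrum(est, fit)
    mask = ((ns.freqs_hz >= 5) & (ns.freqs_hz <= 6)) | (
        (ns.freqs_hz >= 17) & (ns.freqs_hz <= 18)
    )
    rel = ns.residual[0][mask] / fit.predict(ns.freqs_hz)[0][mask]
    slope = linregress(np.log(ns.freqs_hz[mask]), rel).slope
    assert abs(slope) < 0.05


def test_normalize_grid_mismatch_error():
    freqs = np.arange(0.5, 40.0, 0.05)
    est = _flat_estimate(freqs, 8.0 * freqs ** (-1.3))
    fit = fit_power_law(est, [(5, 6)])
    other = _flat_estimate(freqs[:-5], 8.0 * freqs[:-5] ** (-1.3))
    with pytest.raises(ValueError, match="grid"):
        normalize_spectrum(other, fit)


# ---------------------------------------------------------------------------
# band integration
# ---------------------------------------------------------------------------

def _ns_from_residual(freqs, residual, fit_est=None):
    est = fit_est or _flat_estimate(freqs, np.full_like(freqs, 1.0))
    fit = fit_power_law(est, [(freqs[0], freqs[-1])])
    return NormalizedSpectrum(freqs, np.atleast_2d(residual), fit, ["CH0"])


def test_band_integral_rectangle_and_additivity():
    freqs = np.arange(0.5, 40.0, 1.0 / 30.0)
    resid = np.where((freqs >= 9) & (freqs < 16), 1.0, 0.0)
    ns = _ns_from_residual(freqs, resid)
    assert integrate_band(ns, (9, 16)).values[0] == pytest.approx(7.0, abs=1e-9)
    assert integrate_band(ns, (2, 8)).values[0] == pytest.approx(0.0, abs=1e-12)
    a = integrate_band(ns, (9, 12)).values[0]
    b = integrate_band(ns, (12, 16)).values[0]
    assert a + b == pytest.approx(integrate_band(ns, (9, 16)).values[0], abs=1e-12)


def test_band_outside_grid_errors():
    freqs = np.arange(0.5, 40.0, 0.1)
    ns = _ns_from_residual(freqs, np.zeros_like(freqs))
    with pytest.raises(ValueError, match="outside"):
        integrate_band(ns, (45, 50))
    with pytest.raises(ValueError, match="lo < hi"):
        integrate_band(ns, (16, 9))


# ---------------------------------------------------------------------------
# spindle peak
# ---------------------------------------------------------------------------

def _peak_fixture(residual_fn, freqs=None):
    freqs = freqs if freqs is not None else np.arange(0.5, 40.0, 1.0 / 30.0)
    est = _flat_estimate(freqs, 0.01 * freqs ** (-1.0))  # small background
    fit = fit_power_law(est, [(5, 6), (17, 18)])
    return NormalizedSpectrum(freqs, np.atleast_2d(residual_fn(freqs)), fit, ["CH0"])


def test_spindle_peak_vertex_matches_bump_center():
    ns = _peak_fixture(lambda f: _bump(f, 10.9, 4.0))
    (pk,) = find_spindle_peak(ns)
    assert pk.present and pk.freq_hz == pytest.approx(10.9, abs=ns.df_hz)


def test_monotone_residual_has_no_peak():
    ns = _peak_fixture(lambda f: 0.1 * f)
    (pk,) = find_spindle_peak(ns)
    assert not pk.present and pk.freq_hz is None


def test_largest_of_two_bumps_wins():
    ns = _peak_fixture(lambda f: _bump(f, 10.0, 2.0) + _bump(f, 14.0, 1.0))
    (pk,) = find_spindle_peak(ns)
    assert pk.present and pk.freq_hz == pytest.approx(10.0, abs=0.1)


def test_negative_or_subfloor_peaks_are_absent():
    ns = _peak_fixture(lambda f: -_bump(f, 12.0, 3.0))
    (pk,) = find_spindle_peak(ns)
    assert not pk.present
    # peak below the relative-background floor is absent
    freqs = np.arange(0.5, 40.0, 1.0 / 30.0)
    est = _flat_estimate(freqs, 10.0 * freqs ** (-1.0))
    fit = fit_power_law(est, [(5, 6), (17, 18)])
    tiny = NormalizedSpectrum(freqs, np.atleast_2d(_bump(freqs, 12.0, 0.1)), fit, ["CH0"])
    (pk,) = find_spindle_peak(tiny)
    assert not pk.present
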