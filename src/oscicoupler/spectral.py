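"""Spectral estimation and band selection.

Welch PSD, power-law (1/f) slope fitting in semi-log or log-log space,
selection of the subject-specific low-frequency band as the farthest point of
the PSD above the fitted curve, the adaptive filter-bank Hilbert
decomposition, and the PSD of the high-gamma amplitude envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import AnalyticSignal, BandSpec
from .preprocess import design_bandpass_fir, filtfilt_fir


@dataclass
class PowerSpectrum:
    freqs: np.ndarray      # Hz, strictly increasing
    power: np.ndarray      # uV^2/Hz
    window_s: float = 1.0
    overlap: float = 0.5

    def in_range(self, low_hz: float, high_hz: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.freqs >= low_hz) & (self.freqs <= high_hz)
        return self.freqs[m], self.power[m]


@dataclass
class SlopeFit:
    """Linear fit of the PSD decay.

    ``beta`` is the slope of the semi-log regression log10(P) ~ f (the
    regression-coefficient convention); ``chi`` is the exponent of the
    power-law P ~ f^(-chi) obtained from the log-log regression
    log10(P) ~ log10(f).  ``fit_space`` records which fit produced the
    ``predict`` curve used downstream.
    """

    beta: float
    intercept: float
    residuals: np.ndarray
    chi: float
    chi_intercept: float
    fit_range_hz: tuple[float, float]
    fit_space: str = "log-log"

    def predict_log10(self, freqs: np.ndarray) -> np.ndarray:
        """Fitted log10-power at ``freqs`` in the configured fit space."""
        freqs = np.asarray(freqs, dtype=float)
        if self.fit_space == "semi-log":
            return self.intercept + self.beta * freqs
        return self.chi_intercept - self.chi * np.log10(freqs)


def welch_psd(x: np.ndarray, fs: float, window_s: float = 1.0,
              overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD with the configured window length and overlap (Hann taper)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < 2 * nperseg * (1 - overlap) + nperseg * overlap:
        raise ValueError("signal too short for two Welch windows")
    freqs, power = sps.welch(x, fs=fs, nperseg=nperseg,
                             noverlap=int(round(nperseg * overlap)),
                             window="hann", detrend="constant")
    return PowerSpectrum(freqs, power, window_s, overlap)


def fit_powerlaw(psd: PowerSpectrum, fit_range_hz: tuple[float, float] = (2.0, 80.0),
                 fit_space: str = "log-log") -> SlopeFit:
    """Fit the PSD decay by ordinary least squares.

    Both parameterizations are computed: the semi-log slope beta of
    log10(P) ~ f, and the power-law exponent chi from log10(P) ~ log10(f).
    ``fit_space`` selects which curve ``predict_log10`` (and hence band
    selection) uses.
    """
    f, p = psd.in_range(*fit_range_hz)
    m = (f > 0) & (p > 0)
    f, p = f[m], p[m]
    if f.size < 3:
        raise ValueError("fewer than 3 spectral points in the fit range")
    logp = np.log10(p)
    # semi-log: log10 P = intercept + beta * f
    A = np.column_stack([f, np.ones_like(f)])
    (beta, intercept), *_ = np.linalg.lstsq(A, logp, rcond=None)
    # log-log: log10 P = chi_intercept - chi * log10 f
    B = np.column_stack([np.log10(f), np.ones_like(f)])
    (slope_ll, chi_intercept), *_ = np.linalg.lstsq(B, logp, rcond=None)
    chi = -slope_ll
    fit = SlopeFit(beta=float(beta), intercept=float(intercept),
                   residuals=np.empty(0), chi=float(chi),
                   chi_intercept=float(chi_intercept),
                   fit_range_hz=tuple(fit_range_hz), fit_space=fit_space)
    fit.residuals = logp - fit.predict_log10(f)
    return fit


def select_subject_band(psd: PowerSpectrum, fit: SlopeFit,
                        search_range_hz: tuple[float, float] = (4.0, 12.0),
                        bandwidth_hz: float = 4.0) -> BandSpec:
    """Pick the subject-specific low-frequency band.

    The centre is the frequency with the maximal positive distance of
    log10-PSD above the fitted 1/f curve inside ``search_range_hz``; the band
    is centre +/- bandwidth/2.  If no point lies above the fit, the range
    midpoint is returned with the fallback flag set.
    """
    f, p = psd.in_range(*search_range_hz)
    m = p > 0
    f, p = f[m], p[m]
    if f.size == 0:
        raise ValueError("search range contains no spectral points")
    dist = np.log10(p) - fit.predict_log10(f)
    if dist.max() <= 0:
        warnings.warn("no oscillatory peak above the 1/f fit; "
                      "falling back to the search-range midpoint")
        centre = 0.5 * (search_range_hz[0] + search_range_hz[1])
        return BandSpec.from_centre(centre, bandwidth_hz, fallback=True)
    centre = float(f[np.argmax(dist)])
    return BandSpec.from_centre(centre, bandwidth_hz)


def analytic_signal(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
                    cycles: float = 4.0) -> AnalyticSignal:
    """Band-pass (two-way least-squares FIR) then Hilbert transform."""
    taps = design_bandpass_fir(fs, low_hz, high_hz, cycles,
                               n_samples=np.asarray(x).shape[-1])
    filtered = filtfilt_fir(x, taps)
    analytic = sps.hilbert(filtered, axis=-1)
    band = BandSpec(0.5 * (low_hz + high_hz), low_hz, high_hz)
    return AnalyticSignal(np.abs(analytic), np.angle(analytic), band, fs)


def filterbank_centres(f_min: float, f_max: float,
                       spacing_frac: float = 0.1) -> np.ndarray:
    """Adaptive grid: c0 = f_min, c_{k+1} = c_k + spacing_frac * c_k."""
    if f_min < 1:
        raise ValueError("f_min must be >= 1 Hz")
    centres = [float(f_min)]
    while centres[-1] * (1 + spacing_frac) <= f_max + 1e-9:
        centres.append(centres[-1] * (1 + spacing_frac))
    return np.array(centres)


def filterbank_bands(f_min: float, f_max: float, spacing_frac: float = 0.1,
                     bw_frac: float = 0.3) -> list[BandSpec]:
    """Bands of the adaptive filter bank: each centre c spans c +/- bw_frac*c
    (bandwidth 2*bw_frac*c, e.g. 6 Hz at a 10 Hz centre)."""
    return [BandSpec(c, c * (1 - bw_frac), c * (1 + bw_frac))
            for c in filterbank_centres(f_min, f_max, spacing_frac)]


def filterbank_decompose(x: np.ndarray, fs: float, f_min: float, f_max: float,
                         spacing_frac: float = 0.1, bw_frac: float = 0.3,
                         cycles: float = 4.0) -> list[AnalyticSignal]:
    """Filter-bank Hilbert decomposition over the adaptive grid."""
    bands = filterbank_bands(f_min, f_max, spacing_frac, bw_frac)
    if not bands:
        raise ValueError("empty filter-bank grid")
    out = []
    for b in bands:
        if b.high_hz >= fs / 2:
            break
        a = analytic_signal(x, fs, b.low_hz, b.high_hz, cycles)
        a.band = b
        out.append(a)
    if not out:
        raise ValueError("empty filter-bank grid below Nyquist")
    return out


def hg_envelope_psd(x: np.ndarray, fs: float, centre_hz: float,
                    bandwidth_hz: float = 40.0, window_s: float = 1.0) -> PowerSpectrum:
    """PSD of the high-gamma amplitude envelope.

    The signal is band-passed around ``centre_hz`` (the frequency with the
    strongest coupling), the Hilbert amplitude extracted, and the envelope's
    Welch PSD returned; rhythmic entrainment of gamma shows up as a
    low-frequency peak.
    """
    half = bandwidth_hz / 2.0
    if not (centre_hz - half > 30.0 - 1e-9 and centre_hz + half < fs / 2):
        raise ValueError("envelope band must lie inside (30, Nyquist)")
    a = analytic_signal(x, fs, centre_hz - half, centre_hz + half)
    env = a.amplitude - a.amplitude.mean()
    return welch_psd(env, fs, window_s=window_s)


__all__ = [
    "PowerSpectrum",
    "SlopeFit",
    "welch_psd",
    "fit_powerlaw",
    "select_subject_band",
    "analytic_signal",
    "filterbank_centres",
    "filterbank_bands",
    "filterbank_decompose",
    "hg_envelope_psd",
]
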