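"""Directed interaction measures: phase slope index and spectral Granger
causality with permutation nulls.

Phase slope index (PSI)
-----------------------
From epoch-averaged cross- and auto-spectra the complex coherency
``C(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f))`` is formed and

    Psi = Im( sum_{f in band} conj(C(f)) * C(f + df) )

summed over a band of total width 8*df centred at ``nu`` (so a centre of 8 Hz
with 1 Hz resolution spans 4-12 Hz).  A positive Psi means the first signal
leads.  Inputs are the band-passed phase-bearing signal of the modulating
channel and the high-gamma power envelope of the modulated channel; Psi is
tracked over 100 ms sliding windows stepped by 25 ms, with 99.5th-percentile
permutation thresholds per condition.

Spectral Granger causality
--------------------------
Epochs are low-pass filtered and down-sampled (85 Hz / 250 Hz in the standard
chain, handled upstream), a bivariate autoregressive model is fitted across
epoch realizations with the order chosen by AIC, and the Geweke
frequency-domain causality is computed in both directions.  Two permutation
nulls are provided: swapping the channel assignment of whole clips (within a
condition), and flipping the condition labels of clips (for the condition
contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


# ----------------------------------------------------------------- PSI

def psi_band_edges(nu_hz: float, delta_f_hz: float) -> tuple[float, float]:
    """Estimation band of total width 8*delta_f centred at nu."""
    return nu_hz - 4 * delta_f_hz, nu_hz + 4 * delta_f_hz


def _psi_from_segments(xs: np.ndarray, ys: np.ndarray, fs: float,
                       nu_hz: float, delta_f_hz: float) -> float:
    """Psi from a set of (n_epochs, n_samples) segment pairs."""
    n = xs.shape[1]
    taper = np.hanning(n)
    nfft = max(int(round(fs / delta_f_hz)), n)
    X = np.fft.rfft((xs - xs.mean(axis=1, keepdims=True)) * taper, n=nfft)
    Y = np.fft.rfft((ys - ys.mean(axis=1, keepdims=True)) * taper, n=nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sxy = (X * np.conj(Y)).mean(axis=0)
    sxx = (np.abs(X) ** 2).mean(axis=0)
    syy = (np.abs(Y) ** 2).mean(axis=0)
    denom = np.sqrt(sxx * syy)
    denom[denom == 0] = np.inf
    coh = sxy / denom
    lo, hi = psi_band_edges(nu_hz, delta_f_hz)
    df_bins = int(round(delta_f_hz * nfft / fs))
    band = np.where((freqs >= lo - 1e-9) & (freqs <= hi - delta_f_hz + 1e-9))[0]
    if band.size == 0 or band[-1] + df_bins >= coh.size:
        raise ValueError("PSI band outside the resolvable frequency range")
    return float(np.imag(np.sum(np.conj(coh[band]) * coh[band + df_bins])))


@dataclass
class PSIResult:
    window_times: np.ndarray              # window-centre times (s, epoch clock)
    psi: np.ndarray                       # Psi per window
    nu_hz: float
    delta_f_hz: float
    band_hz: tuple[float, float]
    null_threshold: np.ndarray | None = None   # per-window 99.5th pct null
    null_low: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def psi(x_epochs: np.ndarray, y_epochs: np.ndarray, fs: float,
        nu_hz: float, delta_f_hz: float, window_s: float = 0.1,
        step_s: float = 0.025, t0: float = 0.0, n_perm: int = 0,
        q: float = 99.5, seed: int | np.random.Generator = 0) -> PSIResult:
    """Sliding-window PSI from first (x) to second (y) signal epochs.

    ``x_epochs``/``y_epochs``: (n_epochs, n_samples) aligned trials.  For each
    100 ms window the cross-spectra are averaged over epochs and Psi computed
    over the 8*delta_f band around ``nu_hz``.  With ``n_perm`` > 0 the epoch
    pairing between x and y is permuted to build per-window null percentile
    thresholds (``q``-th and its lower mirror).
    """
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y epochs must share shape")
    if x.shape[0] < 8:
        warnings.warn("fewer than 8 epochs; PSI spectra will be noisy")
    lo, hi = psi_band_edges(nu_hz, delta_f_hz)
    if lo <= 0 or hi >= fs / 2:
        raise ValueError("PSI band outside (0, Nyquist)")
    w = int(round(window_s * fs))
    step = max(int(round(step_s * fs)), 1)
    starts = list(range(0, x.shape[1] - w + 1, step))
    if not starts:
        starts = [0]
        w = x.shape[1]
    rng = np.random.default_rng(seed)
    vals = np.empty(len(starts))
    thr_hi = np.empty(len(starts)) if n_perm else None
    thr_lo = np.empty(len(starts)) if n_perm else None
    for k, s0 in enumerate(starts):
        xs, ys = x[:, s0:s0 + w], y[:, s0:s0 + w]
        vals[k] = _psi_from_segments(xs, ys, fs, nu_hz, delta_f_hz)
        if n_perm:
            null = np.empty(n_perm)
            for p in range(n_perm):
                perm = rng.permutation(x.shape[0])
                null[p] = _psi_from_segments(xs, ys[perm], fs, nu_hz, delta_f_hz)
            thr_hi[k] = np.percentile(null, q)
            thr_lo[k] = np.percentile(null, 100 - q)
    times = t0 + (np.array(starts) + w / 2) / fs
    return PSIResult(times, vals, nu_hz, delta_f_hz, (lo, hi), thr_hi, thr_lo)


# ------------------------------------------------------------- Granger

def _var_design(epochs: np.ndarray, order: int,
                start: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stack the VAR regression over epoch realizations.

    ``epochs``: (n_epochs, 2, n_samples).  Returns (targets, predictors) with
    targets (N, 2) and predictors (N, 2*order) where row t of an epoch holds
    [z(t-1), z(t-2), ..., z(t-order)] flattened.  ``start`` (default
    ``order``) is the first target sample, letting order selection condition
    every candidate on the same samples.
    """
    n_ep, n_ch, n_s = epochs.shape
    if start is None:
        start = order
    ys, xs = [], []
    for e in range(n_ep):
        z = epochs[e]
        y = z[:, start:].T                           # (n_s - start, 2)
        cols = [z[:, start - k:n_s - k].T for k in range(1, order + 1)]
        ys.append(y)
        xs.append(np.concatenate(cols, axis=1))
    return np.concatenate(ys), np.concatenate(xs)


def fit_var(epochs: np.ndarray, order: int,
            start: int | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares bivariate VAR pooled across epochs.

    Returns (A, Sigma, aic): coefficient matrices A[k] for lag k+1, the
    ML residual covariance, and the Akaike information criterion.
    """
    y, X = _var_design(epochs, order, start)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.shape[0]
    sigma = resid.T @ resid / n
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        logdet = -np.inf
    n_ch = epochs.shape[1]
    aic = logdet + 2.0 * order * n_ch * n_ch / n
    A = np.stack([coef[k * n_ch:(k + 1) * n_ch].T for k in range(order)])
    return A, sigma, float(aic)


def _is_stable(A: np.ndarray, margin: float = 1e-9) -> bool:
    order, n_ch, _ = A.shape
    companion = np.zeros((order * n_ch, order * n_ch))
    companion[:n_ch] = np.concatenate(list(A), axis=1)
    if order > 1:
        companion[n_ch:, :-n_ch] = np.eye((order - 1) * n_ch)
    return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1 - margin)


def select_var_order(epochs: np.ndarray, order_range: tuple[int, int] = (1, 20)) -> int:
    """AIC-minimizing VAR order over the search range.

    All candidate fits condition on the same target samples (offset by the
    largest candidate order) so their likelihoods are comparable.
    """
    best, best_aic = order_range[0], np.inf
    max_order = min(order_range[1], epochs.shape[2] - 2)
    for m in range(order_range[0], max_order + 1):
        _, _, aic = fit_var(epochs, m, start=max_order)
        if aic < best_aic:
            best, best_aic = m, aic
    return best


@dataclass
class GrangerResult:
    freqs: np.ndarray
    gc_xy: np.ndarray          # x -> y causality per frequency
    gc_yx: np.ndarray
    order: int
    sigma: np.ndarray
    extra: dict = field(default_factory=dict)


def granger_spectral(x_epochs: np.ndarray, y_epochs: np.ndarray, fs: float,
                     f_max: float = 85.0, df: float = 0.5,
                     order: int | None = None,
                     order_range: tuple[int, int] = (1, 20)) -> GrangerResult:
    """Geweke spectral Granger causality between two sets of aligned epochs.

    A bivariate VAR is fitted across epoch realizations (order by AIC unless
    given); the spectral matrix S = H Sigma H* follows from the transfer
    function, and the causality y -> x at each frequency is
    ``ln(S_xx / (Htilde_xx Sigma_xx Htilde_xx*))`` with the standard noise-
    covariance normalization.  Unstable fits are refitted at lower order.
    """
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    epochs = np.stack([x, y], axis=1)     # (n_ep, 2, n_s)
    epochs = epochs - epochs.mean(axis=2, keepdims=True)
    if order is None:
        order = select_var_order(epochs, order_range)
    A, sigma, _ = fit_var(epochs, order)
    while order > 1 and not _is_stable(A):
        warnings.warn(f"unstable VAR fit at order {order}; refitting at {order - 1}")
        order -= 1
        A, sigma, _ = fit_var(epochs, order)

    freqs = np.arange(df, min(f_max, fs / 2 - df) + df / 2, df)
    gc_xy = np.empty(freqs.size)
    gc_yx = np.empty(freqs.size)
    eye = np.eye(2)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / fs * np.arange(1, order + 1))
        Af = eye - np.tensordot(z, A, axes=(0, 0))
        H = np.linalg.inv(Af)
        S = H @ sigma @ H.conj().T
        # y -> x: remove the y-noise route through the normalized transfer fn
        h_xx = H[0, 0] + (sigma[0, 1] / sigma[0, 0]) * H[0, 1]
        intrinsic = (h_xx * sigma[0, 0] * np.conj(h_xx)).real
        gc_yx[i] = max(np.log(max(S[0, 0].real, 1e-300) / max(intrinsic, 1e-300)), 0.0)
        h_yy = H[1, 1] + (sigma[0, 1] / sigma[1, 1]) * H[1, 0]
        intrinsic = (h_yy * sigma[1, 1] * np.conj(h_yy)).real
        gc_xy[i] = max(np.log(max(S[1, 1].real, 1e-300) / max(intrinsic, 1e-300)), 0.0)
    return GrangerResult(freqs, gc_xy, gc_yx, order, sigma)


def granger_null_channel_swap(x_epochs: np.ndarray, y_epochs: np.ndarray,
                              fs: float, n_perm: int = 200,
                              seed: int | np.random.Generator = 0,
                              ci: float = 99.0, **gc_kw) -> dict:
    """Null band for the Granger spectra by swapping clip channel assignment.

    Per permutation each clip's x/y assignment is independently swapped and
    the spectra recomputed; the band is the central ``ci``% interval per
    frequency and direction.
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    obs = granger_spectral(x, y, fs, **gc_kw)
    null_xy = np.empty((n_perm, obs.freqs.size))
    null_yx = np.empty((n_perm, obs.freqs.size))
    for p in range(n_perm):
        flip = rng.random(x.shape[0]) < 0.5
        xp = np.where(flip[:, None], y, x)
        yp = np.where(flip[:, None], x, y)
        res = granger_spectral(xp, yp, fs, order=obs.order, **gc_kw)
        null_xy[p], null_yx[p] = res.gc_xy, res.gc_yx
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    return {
        "freqs": obs.freqs,
        "observed": obs,
        "band_xy": (np.percentile(null_xy, lo_q, axis=0),
                    np.percentile(null_xy, hi_q, axis=0)),
        "band_yx": (np.percentile(null_yx, lo_q, axis=0),
                    np.percentile(null_yx, hi_q, axis=0)),
    }


def granger_condition_contrast(x_epochs: np.ndarray, y_epochs: np.ndarray,
                               labels: np.ndarray, fs: float,
                               conditions: tuple[str, str],
                               n_perm: int = 200,
                               seed: int | np.random.Generator = 0,
                               tail_mass: float = 0.02, **gc_kw) -> dict:
    """Per-frequency significance of the condition difference of the spectra.

    The observed difference (first minus second condition) is compared with a
    null built by flipping clip condition labels; frequencies where it exits
    the two-sided interval (``tail_mass`` total, 1% per side by default) are
    flagged, separately for each direction.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    c0, c1 = conditions

    # fix the model order once (from the first condition's observed data) so
    # every permutation fits comparable models
    order = gc_kw.pop("order", None)
    if order is None:
        first = granger_spectral(x[labels == c0], y[labels == c0], fs, **gc_kw)
        order = first.order
    gc_kw.pop("order_range", None)

    def spectra(lab):
        r0 = granger_spectral(x[lab == c0], y[lab == c0], fs,
                              order=order, **gc_kw)
        r1 = granger_spectral(x[lab == c1], y[lab == c1], fs,
                              order=order, **gc_kw)
        return r0.gc_xy - r1.gc_xy, r0.gc_yx - r1.gc_yx, r0.freqs

    diff_xy, diff_yx, freqs = spectra(labels)
    null_xy = np.empty((n_perm, freqs.size))
    null_yx = np.empty((n_perm, freqs.size))
    for p in range(n_perm):
        d_xy, d_yx, _ = spectra(rng.permutation(labels))
        null_xy[p], null_yx[p] = d_xy, d_yx
    lo_q, hi_q = 100 * tail_mass / 2, 100 * (1 - tail_mass / 2)
    out = {"freqs": freqs, "diff_xy": diff_xy, "diff_yx": diff_yx}
    for name, diff, null in (("xy", diff_xy, null_xy), ("yx", diff_yx, null_yx)):
        lo = np.percentile(null, lo_q, axis=0)
        hi = np.percentile(null, hi_q, axis=0)
        out[f"band_{name}"] = (lo, hi)
        out[f"sig_{name}"] = (diff > hi) | (diff < lo)
    return out


__all__ = [
    "psi_band_edges",
    "PSIResult",
    "psi",
    "fit_var",
    "select_var_order",
    "GrangerResult",
    "granger_spectral",
    "granger_null_channel_swap",
    "granger_condition_contrast",
]
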