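"""Event-locked power: high-gamma time courses with onset/peak latencies,
event-related potentials, and theta-trough-locked time-frequency averages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BandSpec, Epochs, Recording
from .preprocess import lowpass_fir
from .spectral import analytic_signal, filterbank_bands


@dataclass
class HGTimecourse:
    """Per-trial z-scored high-gamma amplitude, baseline corrected."""

    data: np.ndarray                 # trials x channels x samples
    times: np.ndarray                # seconds relative to clip onset
    fs: float
    conditions: np.ndarray
    band: tuple[float, float]
    baseline_source: str             # "session_blank" or "prestim"

    def condition_mean(self, condition: str) -> np.ndarray:
        return self.data[self.conditions == condition].mean(axis=0)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """z-score along the last axis; zero-variance rows map to zeros."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def hg_timecourse(epochs: Epochs, band: tuple[float, float] = (70.0, 180.0),
                  blank_segment: np.ndarray | None = None,
                  prestim_window: tuple[float, float] = (-0.5, 0.0)) -> HGTimecourse:
    """High-gamma amplitude per trial: band-pass, Hilbert amplitude, z-score
    within the whole trial, then subtract the baseline mean.

    The preferred baseline is the session-start blank (``blank_segment``:
    channels x samples of raw signal from the blank screen), whose HG
    amplitude is expressed in each trial's z units before subtraction.
    Without a blank the per-trial pre-stimulus window is used, with a warning.
    """
    fs = epochs.fs
    amp = np.empty_like(epochs.data)
    for i in range(epochs.n_trials):
        amp[i] = analytic_signal(epochs.data[i], fs, band[0], band[1]).amplitude
    mu = amp.mean(axis=-1, keepdims=True)
    sd = amp.std(axis=-1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (amp - mu) / sd_safe

    if blank_segment is not None:
        blank_amp = analytic_signal(np.atleast_2d(blank_segment), fs,
                                    band[0], band[1]).amplitude
        blank_mean = blank_amp.mean(axis=-1)             # per channel
        baseline = (blank_mean[np.newaxis, :, np.newaxis] - mu) / sd_safe
        source = "session_blank"
    else:
        warnings.warn("no session blank supplied; using per-trial "
                      "pre-stimulus baseline")
        times = epochs.times
        m = (times >= prestim_window[0]) & (times < prestim_window[1])
        baseline = z[:, :, m].mean(axis=-1, keepdims=True)
        source = "prestim"
    z = z - baseline
    return HGTimecourse(z, epochs.times, fs, epochs.conditions.copy(),
                        tuple(band), source)


def peak_latency(timecourse: HGTimecourse, significant_window: tuple[int, int] | None,
                 channel: int = 0) -> dict[str, float] | None:
    """Latency (ms) of the maximum of the trial-averaged HG trace per
    condition within the significant window; ties break to the earliest."""
    if significant_window is None:
        return None
    s0, s1 = significant_window
    out = {}
    for cond in np.unique(timecourse.conditions):
        avg = timecourse.condition_mean(str(cond))[channel]
        seg = avg[s0:s1 + 1]
        idx = int(np.argmax(seg))          # argmax returns the first maximum
        out[str(cond)] = float(timecourse.times[s0 + idx] * 1000.0)
    return out


def erp(epochs: Epochs, lowpass_hz: float = 30.0,
        baseline_window: tuple[float, float] = (-0.5, 0.0)) -> dict:
    """Event-related potentials: 30 Hz low-pass, pre-stimulus baseline
    subtraction, condition averages, pointwise two-sample t-tests."""
    fs = epochs.fs
    filt = np.empty_like(epochs.data)
    for i in range(epochs.n_trials):
        filt[i] = lowpass_fir(epochs.data[i], fs, lowpass_hz)
    times = epochs.times
    m = (times >= baseline_window[0]) & (times < baseline_window[1])
    filt = filt - filt[:, :, m].mean(axis=-1, keepdims=True)

    conds = sorted(np.unique(epochs.conditions))
    means = {str(c): filt[epochs.conditions == c].mean(axis=0) for c in conds}
    result = {"times": times, "means": means, "t": None, "p": None}
    if len(conds) == 2:
        a = filt[epochs.conditions == conds[0]]
        b = filt[epochs.conditions == conds[1]]
        tval, pval = stats.ttest_ind(a, b, axis=0)
        result["t"], result["p"] = tval, pval
        result["conditions"] = [str(c) for c in conds]
    return result


def find_phase_troughs(phase: np.ndarray) -> np.ndarray:
    """Trough samples of a wrapped phase series (cosine convention:
    0 = peak, +/-pi = trough).

    The phase passes +/-pi at each trough, where it wraps from near +pi to
    near -pi; each wrap is detected and the adjacent sample whose phase is
    closest to +/-pi is marked (robust to the per-sample phase step, which
    at coarse sampling exceeds any fixed tolerance below -pi).
    """
    phase = np.asarray(phase, dtype=float)
    wraps = np.where(np.diff(phase) < -np.pi)[0]
    if wraps.size == 0:
        return wraps
    before = np.pi - phase[wraps]           # distance of +pi side
    after = phase[wraps + 1] + np.pi        # distance of -pi side
    return np.where(after <= before, wraps + 1, wraps).astype(int)


def trough_locked_tf(x: np.ndarray, fs: float, band: BandSpec,
                     f_min: float = 1.0, f_max: float = 250.0,
                     epoch_s: float = 1.0, modulated: np.ndarray | None = None,
                     n_surrogate: int = 200,
                     seed: int | np.random.Generator = 0) -> dict:
    """Theta-trough-locked average time-frequency map and trough-locked ERP.

    ``x`` supplies the low-frequency phase (troughs at phase < -pi + 0.01);
    ``modulated`` (default: ``x`` itself) is decomposed into the adaptive
    filter bank, each band's signal z-scored, and squared Hilbert amplitude
    (normalized instantaneous power) averaged over 1-s epochs centred on the
    troughs.  Pointwise p-values come from surrogate epochs at random centres.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal")
    if modulated is None:
        modulated = x
    phase = analytic_signal(x, fs, band.low_hz, band.high_hz).phase
    half = int(round(epoch_s * fs / 2))
    troughs = find_phase_troughs(phase)
    troughs = troughs[(troughs >= half) & (troughs < x.size - half)]
    if troughs.size < 5:
        raise ValueError("fewer than 5 usable theta troughs")

    rng = np.random.default_rng(seed)
    bands = [b for b in filterbank_bands(f_min, f_max) if b.high_hz < fs / 2]
    n_t = 2 * half
    tf = np.empty((len(bands), n_t))
    pmap = np.empty((len(bands), n_t))
    rand_centres = rng.integers(half, x.size - half, size=n_surrogate)
    for k, b in enumerate(bands):
        a = analytic_signal(_zscore_rows(modulated[np.newaxis])[0], fs,
                            b.low_hz, b.high_hz)
        power = a.amplitude ** 2
        seg = np.stack([power[c - half:c + half] for c in troughs])
        tf[k] = seg.mean(axis=0)
        null = np.stack([power[c - half:c + half] for c in rand_centres])
        null_mu = null.mean(axis=0)
        # pointwise permutation p: observed trough-locked mean vs surrogates
        ge = (null >= tf[k][np.newaxis]).mean(axis=0)
        pmap[k] = np.minimum(1.0, 2 * np.minimum(ge, 1 - ge) + 1 / n_surrogate)
        del null_mu

    erp_seg = np.stack([x[c - half:c + half] for c in troughs])
    times = (np.arange(n_t) - half) / fs
    return {"times": times, "bands": bands, "tf": tf, "p": pmap,
            "trough_erp": erp_seg.mean(axis=0), "n_troughs": int(troughs.size),
            "troughs": troughs}


__all__ = [
    "HGTimecourse",
    "hg_timecourse",
    "peak_latency",
    "erp",
    "find_phase_troughs",
    "trough_locked_tf",
]
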