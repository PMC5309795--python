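"""Signal conditioning: zero-phase FIR filtering, line-noise regression,
white-matter re-referencing, epoching, and velocity-based saccade detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .containers import ChannelInfo, Epochs, Recording, validate_events


def _fir_length(fs: float, low_hz: float, cycles: float, n_samples: int) -> int:
    """Filter length = cycles * fs / low edge, odd, capped below the signal."""
    numtaps = int(np.ceil(cycles * fs / low_hz))
    numtaps = min(numtaps, max((n_samples - 2) // 3, 3))
    if numtaps % 2 == 0:
        numtaps += 1
    return numtaps


def design_bandpass_fir(fs: float, low_hz: float, high_hz: float,
                        cycles: float = 4.0, n_samples: int = 10**9,
                        trans_frac: float = 0.15) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass with 15% transition bands."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band edges ({low_hz}, {high_hz}) outside (0, {nyq})")
    numtaps = _fir_length(fs, low_hz, cycles, n_samples)
    lo_t = low_hz * (1 - trans_frac)
    hi_t = min(high_hz * (1 + trans_frac), nyq * 0.999)
    bands = [0.0, lo_t, low_hz, high_hz, hi_t, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    taps = sps.firls(numtaps, bands, desired, fs=fs)
    # unity gain at the band centre (least-squares ripple otherwise leaves
    # a ~1% dip there, which compounds over forward-backward passes)
    _, h = sps.freqz(taps, worN=[(low_hz + high_hz) / 2.0], fs=fs)
    return taps / np.abs(h[0])


def filtfilt_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward (zero-phase) FIR filtering along the last axis.

    Implemented with FFT convolution and reflect padding so long filters on
    long recordings stay O(N log N); equivalent to two-way filtering with a
    symmetric FIR.
    """
    x = np.asarray(x, dtype=float)
    pad = min(len(taps), x.shape[-1] - 1)
    xp = np.concatenate(
        [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1)
    t = taps[np.newaxis] if x.ndim > 1 else taps
    y = sps.fftconvolve(xp, t, mode="same", axes=-1)
    y = sps.fftconvolve(y[..., ::-1], t, mode="same", axes=-1)[..., ::-1]
    return y[..., pad:pad + x.shape[-1]]


def bandpass_fir(recording: Recording, low_hz: float, high_hz: float,
                 cycles: float = 4.0) -> Recording:
    """Two-way zero-phase least-squares FIR band-pass of all channels."""
    taps = design_bandpass_fir(recording.fs, low_hz, high_hz, cycles,
                               n_samples=recording.n_samples)
    out = filtfilt_fir(recording.data, taps)
    return recording.copy_with(data=out, bandpass=(low_hz, high_hz))


def lowpass_fir(x: np.ndarray, fs: float, cutoff_hz: float,
                cycles: float = 4.0) -> np.ndarray:
    """Zero-phase FIR low-pass (Hamming window design)."""
    numtaps = _fir_length(fs, cutoff_hz, cycles, x.shape[-1])
    taps = sps.firwin(numtaps, cutoff_hz, fs=fs, window="hamming")
    return filtfilt_fir(x, taps)


def condition_broadband(recording: Recording, low_hz: float = 0.1,
                        high_hz: float = 350.0,
                        target_fs: float = 2000.0) -> Recording:
    """Acquisition-style conditioning: 0.1-350 Hz band-pass, then resample.

    The low edge sits at 0.1 Hz where an FIR of the usual cycles rule would be
    minutes long, so the high-pass side uses a zero-phase 4th-order Butterworth
    (sosfiltfilt) and only the low-pass side is FIR (Hamming).  Down-sampling
    uses polyphase resampling with its default anti-alias design.
    """
    data = recording.data
    if low_hz > 0:
        sos = sps.butter(4, low_hz, btype="highpass", fs=recording.fs, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    if high_hz < recording.fs / 2:
        data = lowpass_fir(data, recording.fs, high_hz)
    if target_fs and target_fs != recording.fs:
        from fractions import Fraction
        frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
        up, down = frac.numerator, frac.denominator
        data = sps.resample_poly(data, up, down, axis=-1)
        out = Recording(data, float(target_fs), list(recording.channels),
                        dict(recording.annotations))
    else:
        out = recording.copy_with(data=data)
    out.annotations["conditioning"] = {"band": (low_hz, high_hz), "fs": out.fs}
    return out


def remove_line_noise(recording: Recording, base_hz: float = 60.0,
                      n_harmonics: int = 3, segment_s: float = 10.0,
                      overlap: float = 0.5) -> Recording:
    """Regression-based removal of line noise and its harmonics.

    Over sliding segments (default 10 s, 50% overlap) the signal is regressed
    on sine/cosine pairs at each harmonic of ``base_hz`` and the fitted
    component is subtracted, blended across segments with a Hann taper.
    """
    if base_hz >= recording.fs / 2:
        raise ValueError("line frequency above Nyquist")
    fs = recording.fs
    n = recording.n_samples
    seg = min(int(round(segment_s * fs)), n)
    step = max(int(round(seg * (1 - overlap))), 1)
    t = np.arange(n) / fs
    harmonics = [k * base_hz for k in range(1, n_harmonics + 1)
                 if k * base_hz < fs / 2]

    fitted = np.zeros_like(recording.data)
    weight = np.zeros(n)
    starts = list(range(0, max(n - seg, 0) + 1, step))
    if starts[-1] + seg < n:
        starts.append(n - seg)
    win = np.hanning(seg) + 1e-6
    for s0 in starts:
        sl = slice(s0, s0 + seg)
        tt = t[sl]
        cols = []
        for f in harmonics:
            cols.append(np.sin(2 * np.pi * f * tt))
            cols.append(np.cos(2 * np.pi * f * tt))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, recording.data[:, sl].T, rcond=None)
        fitted[:, sl] += (X @ beta).T * win
        weight[sl] += win
    fitted /= weight
    return recording.copy_with(data=recording.data - fitted,
                               line_noise_removed=harmonics)


def rereference_white_matter(recording: Recording) -> Recording:
    """Re-reference each grey-matter channel to the nearest white-matter
    contact on the same shaft (nearest by contact index)."""
    wm_by_shaft: dict[str, list[ChannelInfo]] = {}
    for ch in recording.channels:
        if ch.is_white_matter:
            wm_by_shaft.setdefault(ch.shaft, []).append(ch)
    if not wm_by_shaft:
        raise ValueError("no white-matter channel available for re-referencing")

    out = recording.data.copy()
    refs: dict[str, str] = {}
    for i, ch in enumerate(recording.channels):
        if ch.is_white_matter or ch.is_eog:
            continue
        candidates = wm_by_shaft.get(ch.shaft)
        if not candidates:   # fall back to any shaft's white matter
            candidates = [w for lst in wm_by_shaft.values() for w in lst]
        ref = min(candidates, key=lambda w: (abs(w.contact - ch.contact), w.contact))
        out[i] = recording.data[i] - recording.get(ref.name)
        refs[ch.name] = ref.name
    return recording.copy_with(data=out, reference=refs)


def epoch(recording: Recording, events: pd.DataFrame,
          window: tuple[float, float] = (-0.5, 1.5),
          bad_intervals: list[tuple[float, float]] | None = None) -> Epochs:
    """Cut one trial per clip; trials that leave the recording or overlap a
    bad interval are flagged in the mask, not dropped."""
    validate_events(events)
    fs = recording.fs
    n0 = int(round(window[0] * fs))
    n1 = int(round(window[1] * fs))
    n_samp = n1 - n0
    trials, conds, bad = [], [], []
    for _, ev in events.iterrows():
        c = int(round(ev.onset_s * fs))
        i0, i1 = c + n0, c + n1
        flag = i0 < 0 or i1 > recording.n_samples
        if bad_intervals:
            t0, t1 = ev.onset_s + window[0], ev.onset_s + window[1]
            flag = flag or any(t0 < b1 and b0 < t1 for b0, b1 in bad_intervals)
        if i0 < 0 or i1 > recording.n_samples:
            chunk = np.zeros((recording.n_channels, n_samp))
            src0, src1 = max(i0, 0), min(i1, recording.n_samples)
            chunk[:, src0 - i0:src1 - i0] = recording.data[:, src0:src1]
        else:
            chunk = recording.data[:, i0:i1]
        trials.append(chunk)
        conds.append(ev.condition)
        bad.append(flag)
    data = (np.stack(trials) if trials
            else np.empty((0, recording.n_channels, n_samp)))
    return Epochs(data, fs, window, np.array(conds, dtype=object),
                  list(recording.channels), np.array(bad, dtype=bool))


@dataclass
class SaccadeEvents:
    """Detected saccades: peak-velocity sample indices and times."""

    sample: np.ndarray
    time_s: np.ndarray
    velocity: np.ndarray
    threshold: float


def detect_saccades(eog: Recording, percentile: float = 99.0,
                    min_spacing_s: float = 0.2) -> SaccadeEvents:
    """Velocity-threshold saccade detection on a two-channel (x, y) EOG.

    Velocity is the first difference of the Euclidean distance between
    successive (x, y) samples; saccades are marked at local velocity peaks
    above the session-wide ``percentile`` threshold, with a minimum spacing
    (larger peak wins on conflict).
    """
    if eog.n_channels < 2:
        raise ValueError("need two EOG channels (x, y)")
    x, y = eog.data[0], eog.data[1]
    vel = np.hypot(np.diff(x), np.diff(y)) * eog.fs   # units / s
    if vel.size == 0 or np.allclose(vel, vel[0]):
        return SaccadeEvents(np.array([], int), np.array([]), vel, np.inf)
    thr = np.percentile(vel, percentile)
    peaks, _ = sps.find_peaks(vel, height=thr)
    if peaks.size == 0:
        return SaccadeEvents(np.array([], int), np.array([]), vel, thr)
    # greedy keep-largest within the refractory window
    order = np.argsort(vel[peaks])[::-1]
    min_gap = int(round(min_spacing_s * eog.fs))
    kept: list[int] = []
    for p in peaks[order]:
        if all(abs(p - q) >= min_gap for q in kept):
            kept.append(p)
    kept = sorted(kept)
    samples = np.asarray(kept, dtype=int)
    return SaccadeEvents(samples, samples / eog.fs, vel, thr)


def perisaccadic_hg(lfp: Recording, saccades: SaccadeEvents,
                    events: pd.DataFrame | None = None,
                    window: tuple[float, float] = (-0.2, 0.5),
                    baseline: tuple[float, float] = (-0.2, 0.0),
                    band: tuple[float, float] = (70.0, 180.0)) -> dict:
    """High-gamma amplitude epoched around saccades, baseline-corrected and
    compared between conditions with pointwise two-sample t-tests.

    Condition per saccade is looked up from the events table (blank-screen
    saccades are dropped).  Returns traces per condition plus t/p arrays, or
    an empty result (with a warning) when there are no saccades.
    """
    from .spectral import analytic_signal   # local import to avoid a cycle

    if saccades.sample.size == 0:
        warnings.warn("no saccades supplied; returning empty result")
        return {"times": np.array([]), "traces": {}, "t": None, "p": None}

    analytic = analytic_signal(lfp.data, lfp.fs, band[0], band[1])
    amp = analytic.amplitude
    fs = lfp.fs
    n0, n1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    b0, b1 = int(round(baseline[0] * fs)), int(round(baseline[1] * fs))
    times = (np.arange(n0, n1)) / fs

    cond_of = None
    if events is not None:
        from .synthdata import condition_per_sample
        cond_of = condition_per_sample(events, lfp.n_samples, fs)

    per_cond: dict[str, list[np.ndarray]] = {}
    for s in saccades.sample:
        i0, i1 = s + n0, s + n1
        if i0 < 0 or i1 > amp.shape[-1]:
            continue
        cond = "all" if cond_of is None else str(cond_of[s])
        if cond == "":
            continue
        tr = amp[:, i0:i1].copy()
        tr -= tr[:, b0 - n0:b1 - n0].mean(axis=1, keepdims=True)
        per_cond.setdefault(cond, []).append(tr)

    traces = {c: np.stack(v) for c, v in per_cond.items() if v}
    result = {"times": times, "traces": traces, "t": None, "p": None}
    conds = sorted(traces)
    if len(conds) == 2:
        a = traces[conds[0]].mean(axis=1)   # average over channels
        b = traces[conds[1]].mean(axis=1)
        tval, pval = stats.ttest_ind(a, b, axis=0)
        result["t"], result["p"] = tval, pval
        result["conditions"] = conds
    return result


__all__ = [
    "bandpass_fir",
    "design_bandpass_fir",
    "filtfilt_fir",
    "lowpass_fir",
    "condition_broadband",
    "remove_line_noise",
    "rereference_white_matter",
    "epoch",
    "SaccadeEvents",
    "detect_saccades",
    "perisaccadic_hg",
]
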