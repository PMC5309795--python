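"""Inter-electrode coupling measures.

Phase-locking value (PLV) over 1-s windows with the two-step permutation
significance scheme, PLV difference spectra, circular-linear phase-amplitude
coupling (PAC), permutation z-PAC of the condition contrast, and PAC as a
function of time lag.

Conventions
-----------
* PLV between phase series ``phi_i`` and ``phi_j`` over a window of N samples
  is ``|mean_n exp(1j * (phi_i[n] - phi_j[n]))|``; a condition's PLV is the
  arithmetic mean of its window PLVs.
* PAC is the circular-linear correlation between the instantaneous phase of
  the modulating (low-frequency) signal and the instantaneous analytic
  amplitude of the modulated (gamma) signal:
  ``rho = sqrt((r_ca^2 + r_sa^2 - 2 r_ca r_sa r_cs) / (1 - r_cs^2))`` with
  ``r_ca = corr(cos phi, a)``, ``r_sa = corr(sin phi, a)`` and
  ``r_cs = corr(sin phi, cos phi)`` (both circular terms from the same
  modulating phase).
* z-PAC is the z-score of the observed Fisher-z PAC difference
  (aversive - neutral) against a null built by permuting condition labels at
  the clip/segment level; positive z means stronger coupling when aversive.
* In the lag profile a negative lag means the modulating phase precedes the
  modulated amplitude (the modulator leads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .containers import AVERSIVE, NEUTRAL
from .resampling import fisher_z
from .spectral import analytic_signal, filterbank_bands


# ---------------------------------------------------------------- PLV

def window_bounds(n_samples: int, fs: float, window_s: float = 1.0) -> list[tuple[int, int]]:
    """Non-overlapping analysis windows covering the series."""
    w = int(round(window_s * fs))
    if n_samples < w:
        raise ValueError("series shorter than one analysis window")
    return [(i, i + w) for i in range(0, n_samples - w + 1, w)]


def windowed_plv(phase_i: np.ndarray, phase_j: np.ndarray, fs: float,
                 window_s: float = 1.0) -> np.ndarray:
    """PLV per 1-s window between two wrapped phase series."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must have equal length")
    d = np.exp(1j * (phase_i - phase_j))
    return np.array([np.abs(d[a:b].mean()) for a, b in
                     window_bounds(phase_i.size, fs, window_s)])


def plv(phase_i: np.ndarray, phase_j: np.ndarray, fs: float,
        window_s: float = 1.0) -> float:
    """Mean PLV across 1-s windows."""
    return float(windowed_plv(phase_i, phase_j, fs, window_s).mean())


def window_conditions(events, n_samples: int, fs: float,
                      window_s: float = 1.0) -> np.ndarray:
    """Condition label per analysis window (label of the window's midpoint;
    '' for the pre-session blank)."""
    from .synthdata import condition_per_sample
    labels = condition_per_sample(events, n_samples, fs)
    return np.array([str(labels[(a + b) // 2])
                     for a, b in window_bounds(n_samples, fs, window_s)],
                    dtype=object)


@dataclass
class PLVPairResult:
    plv_by_condition: dict[str, float]
    thresholds: dict[str, float]          # within-condition 99th pct nulls
    passed_step1: bool
    difference: float | None = None       # aversive - neutral
    p_value: float | None = None


def plv_contrast(phase_i: np.ndarray, phase_j: np.ndarray,
                 labels: np.ndarray, fs: float, window_s: float = 1.0,
                 n_perm: int = 1000, q: float = 99.0,
                 seed: int | np.random.Generator = 0,
                 conditions: tuple[str, str] = (AVERSIVE, NEUTRAL)) -> PLVPairResult:
    """Two-step PLV significance for one electrode pair.

    Step 1: within each condition, the pairing between the two channels'
    windows is permuted to build a null of condition-mean PLVs; the pair must
    exceed the ``q``-th percentile threshold in BOTH conditions.  Step 2: for
    pairs that pass, window condition labels are permuted to obtain a
    two-sided p-value for the PLV difference (first minus second condition).
    """
    rng = np.random.default_rng(seed)
    bounds = window_bounds(len(phase_i), fs, window_s)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(bounds):
        raise ValueError("one label per analysis window required")
    e_i = np.stack([np.exp(1j * phase_i[a:b]) for a, b in bounds])
    e_j = np.stack([np.exp(1j * phase_j[a:b]) for a, b in bounds])
    pv = np.abs((e_i * np.conj(e_j)).mean(axis=1))      # per-window PLV

    obs = {}
    thresholds = {}
    for cond in conditions:
        idx = np.where(labels == cond)[0]
        if idx.size == 0:
            raise ValueError(f"no windows labelled {cond!r}")
        obs[cond] = float(pv[idx].mean())
        ec_i, ec_j = e_i[idx], e_j[idx]
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(idx.size)
            null[p] = np.abs((ec_i * np.conj(ec_j[perm])).mean(axis=1)).mean()
        thresholds[cond] = float(np.percentile(null, q))

    passed = all(obs[c] > thresholds[c] for c in conditions)
    result = PLVPairResult(obs, thresholds, passed)
    if passed:
        c0, c1 = conditions
        mask = (labels == c0) | (labels == c1)
        sub = pv[mask]
        is_c0 = (labels[mask] == c0)
        diff = sub[is_c0].mean() - sub[~is_c0].mean()
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(is_c0)
            null[p] = sub[perm].mean() - sub[~perm].mean()
        result.difference = float(diff)
        result.p_value = float((1 + np.sum(np.abs(null) >= abs(diff))) / (n_perm + 1))
    return result


def plv_spectrum(x_i: np.ndarray, x_j: np.ndarray, fs: float,
                 labels: np.ndarray, f_min: float = 1.0, f_max: float = 30.0,
                 window_s: float = 1.0,
                 conditions: tuple[str, str] = (AVERSIVE, NEUTRAL),
                 n_dense: int = 200) -> dict:
    """z-scored PLV difference spectrum (first minus second condition).

    The raw signals are decomposed with the adaptive filter bank over
    ``f_min``-``f_max``; per bin the condition PLV difference is computed,
    z-normalized across bins, and smoothed with a fifth-order spline for
    display.  The spline interpolates, so values at bin centres are unchanged.
    """
    bands = [b for b in filterbank_bands(f_min, f_max) if b.high_hz < fs / 2]
    labels = np.asarray(labels, dtype=object)
    centres = np.array([b.centre_hz for b in bands])
    diffs = np.empty(len(bands))
    for k, b in enumerate(bands):
        ph_i = analytic_signal(x_i, fs, b.low_hz, b.high_hz).phase
        ph_j = analytic_signal(x_j, fs, b.low_hz, b.high_hz).phase
        pv = windowed_plv(ph_i, ph_j, fs, window_s)
        c0, c1 = conditions
        diffs[k] = pv[labels == c0].mean() - pv[labels == c1].mean()
    sd = diffs.std()
    z = (diffs - diffs.mean()) / (sd if sd > 0 else 1.0)
    order = min(5, len(bands) - 1)
    spline = make_interp_spline(centres, z, k=order)
    dense_f = np.linspace(centres[0], centres[-1], n_dense)
    return {"freqs": centres, "z": z, "diff": diffs,
            "dense_freqs": dense_f, "smoothed": spline(dense_f),
            "spline": spline}


# ---------------------------------------------------------------- PAC

@dataclass
class PACResult:
    rho: float
    r_ca: float
    r_sa: float
    r_cs: float
    z_rho: float
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def _suffstats(phase: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """Sufficient statistics of the circular-linear correlation.

    Returns [n, Sc, Ss, Sa, Scc, Sss, Saa, Sca, Ssa, Scs] with c = cos(phase),
    s = sin(phase), a = amplitude.  Statistics are additive over segments, so
    any union of segments (e.g. one condition's clips, or a permuted label
    assignment) reduces to a sum of per-segment rows.
    """
    c, s = np.cos(phase), np.sin(phase)
    a = np.asarray(amp, dtype=float)
    return np.array([phase.size, c.sum(), s.sum(), a.sum(),
                     (c * c).sum(), (s * s).sum(), (a * a).sum(),
                     (c * a).sum(), (s * a).sum(), (c * s).sum()])


def _rho_from_stats(st: np.ndarray) -> tuple[float, float, float, float, bool]:
    """(rho, r_ca, r_sa, r_cs, degenerate) from pooled sufficient stats."""
    n, sc, ss, sa, scc, sss, saa, sca, ssa, scs = st
    var_c = scc - sc * sc / n
    var_s = sss - ss * ss / n
    var_a = saa - sa * sa / n
    if var_a <= 1e-300 or var_c <= 0 or var_s <= 0:
        return 0.0, 0.0, 0.0, 0.0, True
    r_ca = (sca - sc * sa / n) / np.sqrt(var_c * var_a)
    r_sa = (ssa - ss * sa / n) / np.sqrt(var_s * var_a)
    r_cs = (scs - sc * ss / n) / np.sqrt(var_c * var_s)
    denom = 1.0 - r_cs ** 2
    if denom <= 1e-12:
        return 0.0, float(r_ca), float(r_sa), float(r_cs), True
    num = r_ca ** 2 + r_sa ** 2 - 2 * r_ca * r_sa * r_cs
    rho = np.sqrt(np.clip(num / denom, 0.0, 1.0))
    return float(rho), float(r_ca), float(r_sa), float(r_cs), False


def pac_circular_linear(phase: np.ndarray, amplitude: np.ndarray) -> PACResult:
    """Circular-linear correlation between a wrapped phase series and a
    non-negative amplitude series.

    A zero-variance amplitude yields rho = 0 with the degenerate flag set.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    rho, r_ca, r_sa, r_cs, degenerate = _rho_from_stats(_suffstats(phase, amplitude))
    z_rho = 0.0 if degenerate else float(fisher_z(min(rho, 1 - 1e-12)))
    return PACResult(rho, r_ca, r_sa, r_cs, z_rho, degenerate)


def segment_bounds_from_events(events, fs: float, n_samples: int) -> tuple[list, np.ndarray]:
    """Clip-level segments (sample bounds) and their condition labels."""
    segs, labels = [], []
    for _, ev in events.iterrows():
        a = int(round(ev.onset_s * fs))
        b = min(int(round((ev.onset_s + ev.duration_s) * fs)), n_samples)
        if b - a > 1:
            segs.append((a, b))
            labels.append(ev.condition)
    return segs, np.array(labels, dtype=object)


def z_pac(phase: np.ndarray, amp: np.ndarray, segments: list[tuple[int, int]],
          labels: np.ndarray, n_perm: int = 1000,
          seed: int | np.random.Generator = 0,
          conditions: tuple[str, str] = (AVERSIVE, NEUTRAL)) -> dict:
    """Permutation z-score of the Fisher-z PAC condition difference.

    ``segments`` are the exchangeable units (clips); per permutation the
    condition labels are reassigned across segments and the pooled
    circular-linear rho recomputed per condition from additive sufficient
    statistics.  Positive z means stronger coupling in ``conditions[0]``.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    stats_per_seg = np.stack([_suffstats(phase[a:b], amp[a:b])
                              for a, b in segments])

    def delta_z(lab: np.ndarray) -> float:
        rhos = []
        for cond in conditions:
            st = stats_per_seg[lab == cond].sum(axis=0)
            rho = _rho_from_stats(st)[0]
            rhos.append(min(rho, 1 - 1e-12))
        return float(fisher_z(rhos[0]) - fisher_z(rhos[1]))

    obs = delta_z(labels)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = delta_z(rng.permutation(labels))
    sd = null.std()
    z = (obs - null.mean()) / (sd if sd > 0 else 1.0)
    # exact two-sided permutation p (the z-score is a normalized summary)
    p_two = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    rho_by_cond = {}
    for cond in conditions:
        st = stats_per_seg[labels == cond].sum(axis=0)
        rho_by_cond[cond] = _rho_from_stats(st)[0]
    return {"z": float(z), "delta_rho_z": obs, "null": null, "p": p_two,
            "rho_by_condition": rho_by_cond}


def z_pac_comodulogram(x_phase: np.ndarray, x_amp: np.ndarray, fs: float,
                       segments: list[tuple[int, int]], labels: np.ndarray,
                       phase_range: tuple[float, float] = (1.0, 30.0),
                       amp_range: tuple[float, float] = (30.0, 250.0),
                       n_perm: int = 200,
                       seed: int | np.random.Generator = 0) -> dict:
    """z-PAC over the (phase frequency) x (amplitude frequency) grid.

    Phase comes from ``x_phase`` filtered over the low-frequency filter-bank
    grid; amplitude from ``x_amp`` over the high-frequency grid.
    """
    rng = np.random.default_rng(seed)
    phase_bands = [b for b in filterbank_bands(*phase_range) if b.high_hz < fs / 2]
    amp_bands = [b for b in filterbank_bands(*amp_range) if b.high_hz < fs / 2]
    phases = [analytic_signal(x_phase, fs, b.low_hz, b.high_hz).phase
              for b in phase_bands]
    amps = [analytic_signal(x_amp, fs, b.low_hz, b.high_hz).amplitude
            for b in amp_bands]
    zmat = np.empty((len(phase_bands), len(amp_bands)))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            zmat[i, j] = z_pac(ph, am, segments, labels, n_perm,
                               rng.integers(2 ** 31))["z"]
    return {"phase_freqs": np.array([b.centre_hz for b in phase_bands]),
            "amp_freqs": np.array([b.centre_hz for b in amp_bands]),
            "z": zmat}


@dataclass
class LagPACProfile:
    """PAC versus time lag; negative lag = modulating phase leads."""

    lags_ms: np.ndarray
    rho: np.ndarray
    z: np.ndarray | None
    peak_lag_ms: float

    def peak_from(self, values: np.ndarray) -> float:
        return float(self.lags_ms[int(np.argmax(values))])


def lag_pac(phase: np.ndarray, amp: np.ndarray, fs: float,
            max_lag_ms: float = 200.0, step_ms: float = 10.0,
            sample_mask: np.ndarray | None = None,
            segments: list[tuple[int, int]] | None = None,
            labels: np.ndarray | None = None, n_perm: int = 0,
            seed: int | np.random.Generator = 0) -> LagPACProfile:
    """PAC magnitude as a function of the lag between phase and amplitude.

    At lag ``L`` ms the correlation is computed between ``phase[n]`` and
    ``amp[n - L*fs/1000]``: a peak at negative L means the amplitude pattern
    reproduces the phase only after a delay, i.e. the modulator leads.
    ``sample_mask`` restricts the correlation to (e.g.) one condition's
    samples.  With ``segments``/``labels`` and ``n_perm`` > 0, the z-PAC
    condition contrast is also computed per lag.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    n = phase.size
    if n <= 2 * int(round(max_lag_ms / 1000 * fs)):
        raise ValueError("signals shorter than twice the maximum lag")
    lags_ms = np.arange(-max_lag_ms, max_lag_ms + step_ms / 2, step_ms)
    rho = np.empty(lags_ms.size)
    zs = np.empty(lags_ms.size) if (n_perm and segments is not None) else None
    rng = np.random.default_rng(seed)
    for k, lag in enumerate(lags_ms):
        off = int(round(lag / 1000.0 * fs))
        lo, hi = max(0, off), min(n, n + off)
        idx = np.arange(lo, hi)
        ph, am = phase[idx], amp[idx - off]
        if sample_mask is not None:
            keep = sample_mask[idx]
            ph, am = ph[keep], am[keep]
        rho[k] = pac_circular_linear(ph, am).rho
        if zs is not None:
            segs_k, labs_k = [], []
            for (a, b), lab in zip(segments, labels):
                a2, b2 = max(a, lo), min(b, hi)
                if b2 - a2 > 1:
                    segs_k.append((a2 - lo, b2 - lo))
                    labs_k.append(lab)
            zs[k] = z_pac(phase[lo:hi], amp[lo - off:hi - off], segs_k,
                          np.array(labs_k, dtype=object), n_perm,
                          rng.integers(2 ** 31))["z"]
    basis = zs if zs is not None else rho
    peak = float(lags_ms[int(np.argmax(basis))])
    return LagPACProfile(lags_ms, rho, zs, peak)


__all__ = [
    "window_bounds",
    "windowed_plv",
    "plv",
    "window_conditions",
    "PLVPairResult",
    "plv_contrast",
    "plv_spectrum",
    "PACResult",
    "pac_circular_linear",
    "segment_bounds_from_events",
    "z_pac",
    "z_pac_comodulogram",
    "LagPACProfile",
    "lag_pac",
]
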