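"""Task-structured synthetic two-region LFP with known, recoverable coupling.

The generator emulates an alternating-block movie-clip session recorded from
depth electrodes in the amygdala and hippocampus: a 1/f (power-law) background,
a low-frequency (theta/alpha) oscillation per channel, a gamma carrier on the
receiver channel whose instantaneous amplitude is entrained by the lagged
low-frequency phase of the driver channel with condition-dependent modulation
depth, evoked high-gamma responses with region-specific onset latencies,
optional 60 Hz line noise, and optional EOG channels with step-like saccade
transients.  Every parameter of the coupling is part of the ground truth, so
downstream estimators (PAC, lag-PAC, PSI, Granger) can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AVERSIVE, NEUTRAL, ChannelInfo, Recording


class ScheduleError(ValueError):
    """Raised when a task schedule cannot be constructed."""


@dataclass
class TaskScheduleParams:
    """Parameters of the alternating-block movie-clip session.

    Defaults reproduce the study conditions: 9 neutral (landscape) blocks
    alternating with 8 aversive (fearful-face) blocks of ~24 s each, tiled by
    70 neutral and 71 aversive clips of 2.8 +/- 1.3 s shown continuously
    without breaks, preceded by a 0.5 s blank screen.
    """

    n_neutral_blocks: int = 9
    n_aversive_blocks: int = 8
    block_duration_s: float = 24.0
    n_neutral_clips: int = 70
    n_aversive_clips: int = 71
    clip_duration_mean_s: float = 2.8
    clip_duration_sd_s: float = 1.3
    pre_session_blank_s: float = 0.5
    first_condition: str = NEUTRAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neutral_blocks < 0 or self.n_aversive_blocks < 0:
            raise ScheduleError("block counts must be non-negative")
        if self.n_neutral_blocks + self.n_aversive_blocks < 1:
            raise ScheduleError("need at least one block")
        if self.block_duration_s <= 0:
            raise ScheduleError("block duration must be positive")


def _split_counts(total: int, n_parts: int, rng: np.random.Generator) -> np.ndarray:
    """Spread `total` clips over `n_parts` blocks as evenly as possible."""
    base, extra = divmod(total, n_parts)
    counts = np.full(n_parts, base, dtype=int)
    counts[rng.choice(n_parts, size=extra, replace=False)] += 1
    return counts


def _truncated_normal(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n positive durations (truncated normal, resampled below 0)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        neg = out <= 0
        if not neg.any():
            break
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    return np.clip(out, 1e-3, None)


def make_task_schedule(params: TaskScheduleParams) -> pd.DataFrame:
    """Build the events table of an alternating-block session.

    Blocks alternate starting with ``params.first_condition``; each block is
    tiled by contiguous clips whose durations are drawn from a truncated
    normal and rescaled so the clips exactly fill the block.  Returns a
    DataFrame with columns onset_s, duration_s, condition, block.
    """
    rng = np.random.default_rng(params.seed)
    n_blocks = params.n_neutral_blocks + params.n_aversive_blocks
    order = [params.first_condition if i % 2 == 0 else
             (AVERSIVE if params.first_condition == NEUTRAL else NEUTRAL)
             for i in range(n_blocks)]
    got = {NEUTRAL: order.count(NEUTRAL), AVERSIVE: order.count(AVERSIVE)}
    want = {NEUTRAL: params.n_neutral_blocks, AVERSIVE: params.n_aversive_blocks}
    if got != want:
        raise ScheduleError(
            f"block counts {want} cannot alternate starting with "
            f"{params.first_condition!r} (alternation gives {got})"
        )
    for cond, n_clips in ((NEUTRAL, params.n_neutral_clips),
                          (AVERSIVE, params.n_aversive_clips)):
        if want[cond] and n_clips < want[cond]:
            raise ScheduleError(
                f"{n_clips} {cond} clips cannot tile {want[cond]} blocks"
            )

    per_block: dict[str, list[int]] = {}
    for cond in (NEUTRAL, AVERSIVE):
        if want[cond]:
            per_block[cond] = list(_split_counts(
                {NEUTRAL: params.n_neutral_clips, AVERSIVE: params.n_aversive_clips}[cond],
                want[cond], rng))

    rows = []
    t = params.pre_session_blank_s
    seen = {NEUTRAL: 0, AVERSIVE: 0}
    for b, cond in enumerate(order):
        n_clips = per_block[cond][seen[cond]]
        seen[cond] += 1
        durs = _truncated_normal(n_clips, params.clip_duration_mean_s,
                                 params.clip_duration_sd_s, rng)
        durs *= params.block_duration_s / durs.sum()   # exact tiling
        onset = t
        for d in durs:
            rows.append((onset, d, cond, b))
            onset += d
        t += params.block_duration_s
    events = pd.DataFrame(rows, columns=["onset_s", "duration_s", "condition", "block"])
    return events


@dataclass
class CouplingGroundTruth:
    """Ground-truth parameters of the simulated driver->receiver coupling.

    The driver (amygdala) carries a stochastic narrowband theta/alpha
    oscillation.  Its phase, lagged by ``conduction_lag_ms``, entrains the
    receiver (hippocampus) gamma amplitude with a condition-specific
    modulation depth, and the lagged oscillation itself is mixed into the
    receiver's low-frequency component with weight ``phase_coupling_*``
    (defaulting to the modulation depths), producing the inter-regional
    theta synchrony and directed low-frequency influence that PLV, PSI and
    Granger analyses measure.  ``psd_exponent_chi`` is the exponent chi of
    the power-law background P ~ f^(-chi).
    """

    driver_channel: str = "amy1"
    receiver_channel: str = "hpc1"
    f_low_driver_hz: float = 6.0
    f_low_receiver_hz: float = 6.5
    f_gamma_receiver_hz: float = 100.0
    gamma_bandwidth_hz: float = 40.0
    modulation_depth_aversive: float = 0.6
    modulation_depth_neutral: float = 0.3
    conduction_lag_ms: float = 15.0
    phase_coupling_aversive: float | None = None   # None -> modulation depth
    phase_coupling_neutral: float | None = None
    osc_bandwidth_hz: float = 2.0
    psd_exponent_chi: float = 2.0
    hg_onset_ms: dict = field(default_factory=lambda: {"amy1": 120.0, "hpc1": 240.0})
    line_noise_amp: float = 0.0
    line_noise_hz: float = 60.0
    n_line_harmonics: int = 3
    # amplitude bookkeeping (microvolt-scale weights, not study-constrained)
    noise_scale: float = 1.0
    osc_amp: float = 1.0
    gamma_base: float = 0.3
    gamma_scale: float = 0.5
    evoked_hg_amp_aversive: float = 0.5
    evoked_hg_amp_neutral: float = 0.0
    evoked_rise_ms: float = 100.0
    evoked_hold_ms: float = 400.0
    evoked_fall_ms: float = 200.0

    def __post_init__(self) -> None:
        for d in (self.modulation_depth_aversive, self.modulation_depth_neutral):
            if not 0.0 <= d <= 1.0:
                raise ValueError("modulation depths must lie in [0, 1]")
        if not (self.f_gamma_receiver_hz >= 30.0 > self.f_low_driver_hz):
            raise ValueError("need f_gamma >= 30 Hz > f_low")
        if abs(self.conduction_lag_ms) > 200.0:
            raise ValueError("conduction lag outside the +/-200 ms analysis range")


def powerlaw_noise(n: int, chi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped so its PSD falls as f^(-chi).

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to f^(-chi/2); the DC bin is zeroed.  The output has unit
    standard deviation.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-chi / 2.0)
    spec *= shape
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def condition_per_sample(events: pd.DataFrame, n: int, fs: float) -> np.ndarray:
    """Label each sample 'aversive' / 'neutral' / '' (blank) from the events."""
    labels = np.full(n, "", dtype=object)
    for _, ev in events.iterrows():
        i0 = int(round(ev.onset_s * fs))
        i1 = int(round((ev.onset_s + ev.duration_s) * fs))
        labels[i0:min(i1, n)] = ev.condition
    return labels


def _evoked_pulse(fs: float, truth: CouplingGroundTruth) -> np.ndarray:
    """Half-cosine rise, plateau, half-cosine fall; unit peak amplitude."""
    n_rise = max(int(round(truth.evoked_rise_ms / 1000 * fs)), 1)
    n_hold = int(round(truth.evoked_hold_ms / 1000 * fs))
    n_fall = max(int(round(truth.evoked_fall_ms / 1000 * fs)), 1)
    rise = (1 - np.cos(np.pi * np.arange(n_rise) / n_rise)) / 2
    fall = (1 + np.cos(np.pi * np.arange(n_fall) / n_fall)) / 2
    return np.concatenate([rise, np.ones(n_hold), fall])


def _evoked_envelope(events: pd.DataFrame, n: int, fs: float,
                     onset_ms: float, truth: CouplingGroundTruth) -> np.ndarray:
    """Evoked HG amplitude envelope for one channel across the session."""
    amp = {AVERSIVE: truth.evoked_hg_amp_aversive, NEUTRAL: truth.evoked_hg_amp_neutral}
    pulse = _evoked_pulse(fs, truth)
    env = np.zeros(n)
    for _, ev in events.iterrows():
        a = amp.get(ev.condition, 0.0)
        if a == 0.0:
            continue
        i0 = int(round((ev.onset_s + onset_ms / 1000.0) * fs))
        i1 = min(i0 + len(pulse), n)
        if i0 < n:
            env[i0:i1] += a * pulse[: i1 - i0]
    return env


def narrowband_oscillation(n: int, f_centre: float, bandwidth: float,
                           fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stochastic narrowband oscillation (frequency-domain
    shaped Gaussian noise with a Gaussian profile around ``f_centre``)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = max(bandwidth / 2.0, 1e-3)
    spec *= np.exp(-0.5 * ((freqs - f_centre) / sigma) ** 2)
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_lfp(schedule: pd.DataFrame, truth: CouplingGroundTruth,
                 fs: float = 2000.0, seed: int = 0,
                 include_white_matter: bool = True) -> Recording:
    """Simulate the two-region session defined by ``schedule`` and ``truth``.

    Channels: the driver contact (amygdala-BLA), the receiver contact
    (hippocampus-CA1), and optionally one white-matter contact per shaft.
    The receiver gamma amplitude during a block is
    ``base + depth * (1 + cos(phi_driver(t - lag))) / 2`` with the block's
    condition-specific depth (0 during the blank), where ``phi_driver`` is
    the analytic phase of the driver's stochastic narrowband oscillation;
    the lagged driver oscillation is also mixed into the receiver's
    low-frequency component with the condition's phase-coupling weight.
    The driver gamma amplitude is unmodulated, so coupling exists only
    driver -> receiver.  Deterministic given ``seed``.
    """
    from scipy.signal import hilbert

    if fs < 4 * truth.f_gamma_receiver_hz:
        raise ValueError("fs must be at least 4x the gamma carrier frequency")
    if abs(truth.conduction_lag_ms) > 200.0:
        raise ValueError("conduction lag outside the +/-200 ms analysis range")

    rng = np.random.default_rng(seed)
    t_end = float(schedule.onset_s.iloc[-1] + schedule.duration_s.iloc[-1])
    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    labels = condition_per_sample(schedule, n, fs)

    def per_condition(av: float, ne: float) -> np.ndarray:
        out = np.zeros(n)
        out[labels == AVERSIVE] = av
        out[labels == NEUTRAL] = ne
        return out

    depth = per_condition(truth.modulation_depth_aversive,
                          truth.modulation_depth_neutral)
    w_av = (truth.phase_coupling_aversive
            if truth.phase_coupling_aversive is not None
            else truth.modulation_depth_aversive)
    w_ne = (truth.phase_coupling_neutral
            if truth.phase_coupling_neutral is not None
            else truth.modulation_depth_neutral)
    weight = per_condition(w_av, w_ne)

    # driver low-frequency oscillation: stochastic narrowband process
    osc_d = narrowband_oscillation(n, truth.f_low_driver_hz,
                                   truth.osc_bandwidth_hz, fs, rng)
    phase_driver = np.angle(hilbert(osc_d))
    lag_n = int(round(truth.conduction_lag_ms / 1000.0 * fs))
    osc_d_lagged = np.roll(osc_d, lag_n)          # positive lag: driver leads
    phase_lagged = np.roll(phase_driver, lag_n)

    line = np.zeros(n)
    if truth.line_noise_amp > 0:
        for k in range(1, truth.n_line_harmonics + 1):
            f_k = k * truth.line_noise_hz
            if f_k < fs / 2:
                line += (truth.line_noise_amp / k) * np.sin(
                    2 * np.pi * f_k * t + rng.uniform(0, 2 * np.pi))

    def background(chi: float) -> np.ndarray:
        return truth.noise_scale * powerlaw_noise(n, chi, fs, rng)

    chi = truth.psd_exponent_chi
    # stochastic narrowband gamma carriers: real high-gamma amplitude
    # fluctuates, so the envelope is env * (carrier's own Rayleigh-like
    # amplitude), keeping PAC rho in a realistic range
    carrier_rx = narrowband_oscillation(n, truth.f_gamma_receiver_hz,
                                        truth.gamma_bandwidth_hz, fs, rng)
    carrier_dr = narrowband_oscillation(n, truth.f_gamma_receiver_hz,
                                        truth.gamma_bandwidth_hz, fs, rng)

    # driver: own theta/alpha rhythm + unmodulated gamma + evoked HG
    drv_onset = truth.hg_onset_ms.get(truth.driver_channel, 120.0)
    env_dr = (truth.gamma_base
              + _evoked_envelope(schedule, n, fs, drv_onset, truth))
    driver = (background(chi)
              + truth.osc_amp * osc_d
              + truth.gamma_scale * env_dr * carrier_dr
              + line)

    # receiver: own rhythm mixed with the lagged driver rhythm, plus gamma
    # entrained by the lagged driver phase
    rcv_onset = truth.hg_onset_ms.get(truth.receiver_channel, 240.0)
    osc_r = narrowband_oscillation(n, truth.f_low_receiver_hz,
                                   truth.osc_bandwidth_hz, fs, rng)
    env_rx = (truth.gamma_base
              + depth * (1 + np.cos(phase_lagged)) / 2
              + _evoked_envelope(schedule, n, fs, rcv_onset, truth))
    receiver = (background(chi)
                + truth.osc_amp * ((1 - weight) * osc_r + weight * osc_d_lagged)
                + truth.gamma_scale * env_rx * carrier_rx
                + line)

    data = [driver, receiver]
    channels = [
        ChannelInfo(truth.driver_channel, "amygdala-BLA", shaft="A", contact=1),
        ChannelInfo(truth.receiver_channel, "hippocampus-CA1", shaft="H", contact=1),
    ]
    if include_white_matter:
        for shaft in ("A", "H"):
            data.append(background(chi) + line)
            channels.append(ChannelInfo(f"{shaft.lower()}wm", "white-matter",
                                        shaft=shaft, contact=2))

    ground_truth = {
        "driver_channel": truth.driver_channel,
        "receiver_channel": truth.receiver_channel,
        "f_low_driver_hz": truth.f_low_driver_hz,
        "f_low_receiver_hz": truth.f_low_receiver_hz,
        "f_gamma_receiver_hz": truth.f_gamma_receiver_hz,
        "modulation_depth_aversive": truth.modulation_depth_aversive,
        "modulation_depth_neutral": truth.modulation_depth_neutral,
        "conduction_lag_ms": truth.conduction_lag_ms,
        "psd_exponent_chi": truth.psd_exponent_chi,
        "hg_onset_ms": dict(truth.hg_onset_ms),
        "line_noise_amp": truth.line_noise_amp,
    }
    return Recording(np.vstack(data), fs, channels,
                     annotations={"seed": seed, "ground_truth": ground_truth})


def simulate_eog(schedule: pd.DataFrame, saccade_rate_hz: float = 2.0,
                 fs: float = 2000.0, seed: int = 0,
                 refractory_s: float = 0.2) -> Recording:
    """Two EOG channels (horizontal, vertical) with step-like saccades.

    Saccade times follow a Poisson process thinned to a 200 ms refractory
    period; each saccade is a smoothed position step of random direction.
    Ground-truth times are stored in ``annotations['saccade_times_s']``.
    """
    if saccade_rate_hz < 0:
        raise ValueError("saccade rate must be non-negative")
    rng = np.random.default_rng(seed)
    t_end = float(schedule.onset_s.iloc[-1] + schedule.duration_s.iloc[-1])
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    times: list[float] = []
    if saccade_rate_hz > 0:
        tt = rng.exponential(1.0 / saccade_rate_hz)
        while tt < t_end - 0.05:
            if not times or tt - times[-1] >= refractory_s:
                times.append(tt)
            tt += rng.exponential(1.0 / saccade_rate_hz)

    # slow drift background
    drift_h = powerlaw_noise(n, 2.5, fs, rng) * 20.0
    drift_v = powerlaw_noise(n, 2.5, fs, rng) * 20.0
    step_len = max(int(0.02 * fs), 2)   # ~20 ms position change
    ramp = (1 - np.cos(np.pi * np.arange(step_len) / step_len)) / 2
    h = drift_h.copy()
    v = drift_v.copy()
    for st in times:
        i0 = int(round(st * fs))
        theta = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(50.0, 150.0)
        for sig, comp in ((h, np.cos(theta)), (v, np.sin(theta))):
            i1 = min(i0 + step_len, n)
            sig[i0:i1] += amp * comp * ramp[: i1 - i0]
            sig[i1:] += amp * comp

    channels = [ChannelInfo("eogH", "EOG"), ChannelInfo("eogV", "EOG")]
    return Recording(np.vstack([h, v]), fs, channels,
                     annotations={"seed": seed, "saccade_times_s": list(times)})


__all__ = [
    "ScheduleError",
    "TaskScheduleParams",
    "CouplingGroundTruth",
    "make_task_schedule",
    "simulate_lfp",
    "simulate_eog",
    "powerlaw_noise",
    "condition_per_sample",
]
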