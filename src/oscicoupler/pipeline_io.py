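"""Formats, configuration and orchestration.

Recordings are interchanged as an uncompressed array container (``.npy``)
with a JSON sidecar (sampling rate, channel metadata, ground truth) and a
tab-separated events table; EDF input is also accepted (read through mne).
``run_pipeline`` chains synthesis, preprocessing, spectral band selection,
event-locked high gamma, coupling and directionality into a report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, directionality, eventpower, preprocess, resampling, spectral
from .containers import (AVERSIVE, NEUTRAL, ChannelInfo, Recording,
                         validate_events)
from .synthdata import (CouplingGroundTruth, TaskScheduleParams,
                        make_task_schedule, simulate_lfp)

__version__ = "0.1.0"


# ------------------------------------------------------------------ I/O

def save_recording(recording: Recording, outdir: str | Path, stem: str,
                   events: pd.DataFrame | None = None) -> Path:
    """Write ``stem.npy`` + ``stem.json`` sidecar (+ ``stem_events.tsv``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / f"{stem}.npy", recording.data)
    sidecar = {
        "fs": recording.fs,
        "channels": [asdict(ch) for ch in recording.channels],
        "annotations": _jsonable(recording.annotations),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    if events is not None:
        events.to_csv(outdir / f"{stem}_events.tsv", sep="\t", index=False)
    return outdir / f"{stem}.npy"


def load_events(path: str | Path, duration_s: float | None = None) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    return validate_events(events, duration_s)


def load_recording(path: str | Path,
                   sidecar: str | Path | None = None) -> Recording:
    """Load a recording from ``.npy`` (+ JSON sidecar) or ``.edf``.

    The sidecar carries the channel metadata; for EDF input a sampling-rate
    mismatch between header and sidecar is rejected, and channels present in
    the data but missing from the sidecar are a hard error.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"channel sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    channels = [ChannelInfo(**c) for c in meta["channels"]]
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6      # volts -> microvolts
        fs = float(raw.info["sfreq"])
        if abs(fs - meta["fs"]) > 1e-6:
            raise ValueError(
                f"sampling rate mismatch: header {fs} Hz vs sidecar {meta['fs']} Hz")
        names = raw.ch_names
    else:
        data = np.load(path)
        fs = float(meta["fs"])
        names = [c.name for c in channels]
    by_name = {c.name: c for c in channels}
    missing = [nm for nm in names if nm not in by_name]
    if missing:
        raise ValueError(f"channels without sidecar metadata: {missing}")
    ordered = [by_name[nm] for nm in names]
    return Recording(data, fs, ordered, meta.get("annotations", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ----------------------------------------------------------- selection

def select_pairs(channels: list[ChannelInfo], n_amygdala: int = 3,
                 n_hippocampus: int = 4) -> list[tuple[str, str]]:
    """Medial-contact electrode pairs: the ``n_amygdala`` most medial
    amygdala contacts crossed with the ``n_hippocampus`` most medial
    hippocampal contacts (contact 1 = most medial); fewer contacts than
    requested uses all available with a warning."""
    def most_medial(region: str, n: int) -> list[ChannelInfo]:
        cands = sorted((c for c in channels
                        if c.macro_region == region and not c.is_white_matter),
                       key=lambda c: c.contact)
        if len(cands) < n:
            warnings.warn(f"only {len(cands)} {region} contacts available "
                          f"(rule asked for {n}); using all")
        return cands[:n]

    amy = most_medial("amygdala", n_amygdala)
    hpc = most_medial("hippocampus", n_hippocampus)
    return [(a.name, h.name) for a in amy for h in hpc]


def select_best_pair(results: dict[tuple[str, str], coupling.PLVPairResult]
                     ) -> tuple[str, str] | None:
    """Most significant phase-coupling pair among those passing step 1.

    Ordered by p-value, then by larger difference; remaining ties fall to the
    lexically first pair name (lower contact indices win).
    """
    passed = {k: v for k, v in results.items() if v.passed_step1}
    if not passed:
        return None
    return min(passed, key=lambda k: (
        passed[k].p_value if passed[k].p_value is not None else 1.0,
        -(passed[k].difference or 0.0), k))


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Everything one run needs; seeds are explicit for reproducibility."""

    out_dir: str = "oscicoupler_out"
    seed: int = 0
    fs_analysis: float = 2000.0
    fs_granger: float = 250.0
    granger_lowpass_hz: float = 85.0
    n_perm: int = 1000
    n_perm_heavy: int = 200          # comodulogram / Granger permutations
    band_search_hz: tuple = (4.0, 12.0)
    band_fit_hz: tuple = (2.0, 80.0)
    bandwidth_hz: float = 4.0
    hg_band: tuple = (70.0, 180.0)
    epoch_window: tuple = (-0.5, 1.5)
    n_amygdala: int = 3
    n_hippocampus: int = 4
    comodulogram_phase_hz: tuple = (2.0, 12.0)
    comodulogram_amp_hz: tuple = (60.0, 160.0)
    remove_line_noise: bool = False
    schedule: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(asdict(self))))


def synthesize(config: PipelineConfig, outdir: Path | None = None
               ) -> tuple[Recording, pd.DataFrame]:
    """Generate the synthetic session described by the config."""
    sched_params = TaskScheduleParams(**{"seed": config.seed, **config.schedule})
    events = make_task_schedule(sched_params)
    truth = CouplingGroundTruth(**config.truth)
    rec = simulate_lfp(events, truth, fs=config.fs_analysis, seed=config.seed)
    if outdir is not None:
        save_recording(rec, outdir, "recording", events=events)
    return rec, events


# -------------------------------------------------------------- pipeline

def run_pipeline(config: PipelineConfig,
                 recording: Recording | None = None,
                 events: pd.DataFrame | None = None) -> dict:
    """Run synth -> preprocess -> spectral -> event power -> coupling ->
    directionality and write a structured report bundle to ``out_dir``.

    Partial results are preserved with an error manifest if a stage fails.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _jsonable(asdict(config)), "stages": []}
    report: dict = {}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        manifest["stages"].append(name)

    try:
        if recording is None:
            stage("synth")
            recording, events = synthesize(config, outdir)
        elif events is None:
            raise ValueError("events table required with a supplied recording")
        validate_events(events, recording.duration_s)
        fs = recording.fs

        stage("preprocess")
        rec = recording
        if config.remove_line_noise:
            rec = preprocess.remove_line_noise(rec)
        has_wm = any(c.is_white_matter for c in rec.channels)
        if has_wm:
            rec = preprocess.rereference_white_matter(rec)
        grey = [c for c in rec.channels
                if not (c.is_white_matter or c.is_eog)]
        epochs = preprocess.epoch(rec.pick([c.name for c in grey]), events,
                                  window=tuple(config.epoch_window))

        stage("spectral")
        bands: dict[str, dict] = {}
        for ch in grey:
            psd = spectral.welch_psd(rec.get(ch.name), fs)
            fit = spectral.fit_powerlaw(psd, tuple(config.band_fit_hz))
            band = spectral.select_subject_band(
                psd, fit, tuple(config.band_search_hz), config.bandwidth_hz)
            bands[ch.name] = {"band": band, "chi": fit.chi, "beta": fit.beta,
                              "fallback": band.fallback}
        report["bands"] = {k: {"centre_hz": v["band"].centre_hz,
                               "low_hz": v["band"].low_hz,
                               "high_hz": v["band"].high_hz,
                               "chi": v["chi"], "beta": v["beta"],
                               "fallback": v["fallback"]}
                           for k, v in bands.items()}

        stage("eventpower")
        blank_s = float(events.onset_s.min())
        blank = (rec.pick([c.name for c in grey]).data[:, :int(blank_s * fs)]
                 if blank_s >= 0.25 else None)
        hg = eventpower.hg_timecourse(epochs, band=tuple(config.hg_band),
                                      blank_segment=blank)
        latencies = {}
        stim_sample = int(round(-config.epoch_window[0] * fs))
        for ci, ch in enumerate(grey):
            res = resampling.cluster_permutation_test(
                hg.data[hg.conditions == AVERSIVE][:, ci],
                hg.data[hg.conditions == NEUTRAL][:, ci],
                n_perm=config.n_perm, seed=rng.integers(2 ** 31))
            # evoked onset: first post-stimulus sample of a significant
            # aversive > neutral cluster
            oo = resampling.onset_offset_from_clusters(
                res, min_sample=stim_sample, sign=+1)
            entry = {"onset_ms": None, "offset_ms": None, "peaks_ms": None}
            if oo is not None:
                entry["onset_ms"] = float(hg.times[oo[0]] * 1000)
                entry["offset_ms"] = float(hg.times[oo[1]] * 1000)
                entry["peaks_ms"] = eventpower.peak_latency(hg, oo, channel=ci)
            latencies[ch.name] = entry
        report["hg_latencies"] = latencies

        stage("coupling")
        pairs = select_pairs(grey, config.n_amygdala, config.n_hippocampus)
        labels = coupling.window_conditions(events, rec.n_samples, fs)
        phases = {}
        plv_results = {}
        for a_name, h_name in pairs:
            for nm in (a_name, h_name):
                if nm not in phases:
                    b = bands[nm]["band"]
                    phases[nm] = spectral.analytic_signal(
                        rec.get(nm), fs, b.low_hz, b.high_hz).phase
            plv_results[(a_name, h_name)] = coupling.plv_contrast(
                phases[a_name], phases[h_name], labels, fs,
                n_perm=config.n_perm, seed=rng.integers(2 ** 31))
        best = select_best_pair(plv_results)
        report["plv"] = {
            f"{a}->{h}": {"plv": r.plv_by_condition, "passed": r.passed_step1,
                          "difference": r.difference, "p": r.p_value}
            for (a, h), r in plv_results.items()}
        report["best_pair"] = list(best) if best else None

        direction_calls = {"pac": "none", "psi": "none", "granger": "none"}
        if best is not None:
            a_name, h_name = best
            segs, seg_labels = coupling.segment_bounds_from_events(
                events, fs, rec.n_samples)
            amp_h = spectral.analytic_signal(rec.get(h_name), fs,
                                             *config.hg_band).amplitude
            amp_a = spectral.analytic_signal(rec.get(a_name), fs,
                                             *config.hg_band).amplitude
            z_fwd = coupling.z_pac(phases[a_name], amp_h, segs, seg_labels,
                                   config.n_perm, rng.integers(2 ** 31))
            z_rev = coupling.z_pac(phases[h_name], amp_a, segs, seg_labels,
                                   config.n_perm, rng.integers(2 ** 31))
            report["z_pac"] = {f"{a_name}->{h_name}": z_fwd["z"],
                               f"{h_name}->{a_name}": z_rev["z"],
                               "rho_forward": z_fwd["rho_by_condition"],
                               "rho_reverse": z_rev["rho_by_condition"]}
            if z_fwd["z"] > 2.33 and z_fwd["z"] > z_rev["z"]:
                direction_calls["pac"] = f"{a_name}->{h_name}"
            elif z_rev["z"] > 2.33:
                direction_calls["pac"] = f"{h_name}->{a_name}"

            como = coupling.z_pac_comodulogram(
                rec.get(a_name), rec.get(h_name), fs, segs, seg_labels,
                tuple(config.comodulogram_phase_hz),
                tuple(config.comodulogram_amp_hz),
                n_perm=config.n_perm_heavy, seed=rng.integers(2 ** 31))
            pd.DataFrame(como["z"], index=como["phase_freqs"],
                         columns=como["amp_freqs"]).to_csv(
                outdir / "comodulogram.tsv", sep="\t")
            report["comodulogram_max_z"] = float(como["z"].max())

            from .synthdata import condition_per_sample
            samp_labels = condition_per_sample(events, rec.n_samples, fs)
            mask = samp_labels == AVERSIVE
            lag_fwd = coupling.lag_pac(phases[a_name], amp_h, fs,
                                       sample_mask=mask)
            lag_rev = coupling.lag_pac(phases[h_name], amp_a, fs,
                                       sample_mask=mask)
            report["lag_pac"] = {
                f"{a_name}->{h_name}_peak_ms": lag_fwd.peak_lag_ms,
                f"{h_name}->{a_name}_peak_ms": lag_rev.peak_lag_ms}

            stage("directionality")
            b = bands[a_name]["band"]
            mod = preprocess.bandpass_fir(rec.pick([a_name]),
                                          b.low_hz, b.high_hz).data[0]
            ep_mod = preprocess.epoch(
                Recording(mod[np.newaxis], fs, [rec.channels[rec.index_of(a_name)]]),
                events, window=(0.0, 1.5))
            ep_env = preprocess.epoch(
                Recording(amp_h[np.newaxis], fs, [rec.channels[rec.index_of(h_name)]]),
                events, window=(0.0, 1.5))
            av = ep_mod.conditions == AVERSIVE
            psi_res = directionality.psi(
                ep_mod.data[av][:, 0], ep_env.data[av][:, 0], fs,
                nu_hz=b.centre_hz, delta_f_hz=1.0,
                n_perm=config.n_perm_heavy, seed=rng.integers(2 ** 31))
            sig_pos = (psi_res.null_threshold is not None and
                       np.any(psi_res.psi > psi_res.null_threshold))
            report["psi"] = {"mean": float(psi_res.psi.mean()),
                             "band_hz": psi_res.band_hz,
                             "n_sig_windows": int(np.sum(
                                 psi_res.psi > psi_res.null_threshold))
                             if psi_res.null_threshold is not None else 0}
            if sig_pos and psi_res.psi.mean() > 0:
                direction_calls["psi"] = f"{a_name}->{h_name}"

            # Granger chain: low-pass, down-sample, first 1.5 s of each clip
            x = preprocess.lowpass_fir(rec.get(a_name), fs,
                                       config.granger_lowpass_hz)
            y = preprocess.lowpass_fir(rec.get(h_name), fs,
                                       config.granger_lowpass_hz)
            from fractions import Fraction
            fr = Fraction(config.fs_granger / fs).limit_denominator(10000)
            from scipy.signal import resample_poly
            x = resample_poly(x, fr.numerator, fr.denominator)
            y = resample_poly(y, fr.numerator, fr.denominator)
            fs_g = config.fs_granger
            rec_g = Recording(np.vstack([x, y]), fs_g,
                              [rec.channels[rec.index_of(a_name)],
                               rec.channels[rec.index_of(h_name)]])
            ep_g = preprocess.epoch(rec_g, events, window=(0.0, 1.5))
            keep = ~ep_g.bad
            gc = directionality.granger_condition_contrast(
                ep_g.data[keep][:, 0], ep_g.data[keep][:, 1],
                ep_g.conditions[keep], fs_g, (AVERSIVE, NEUTRAL),
                n_perm=config.n_perm_heavy, seed=rng.integers(2 ** 31))
            low = gc["freqs"] <= 12.0
            report["granger"] = {
                "sig_fraction_xy_low": float(gc["sig_xy"][low].mean()),
                "sig_fraction_yx_low": float(gc["sig_yx"][low].mean()),
                "mean_diff_xy_low": float(gc["diff_xy"][low].mean()),
                "mean_diff_yx_low": float(gc["diff_yx"][low].mean())}
            if (gc["sig_xy"][low].any()
                    and gc["diff_xy"][low].mean() > gc["diff_yx"][low].mean()):
                direction_calls["granger"] = f"{a_name}->{h_name}"
        report["direction_calls"] = direction_calls

        manifest["status"] = "ok"
    except Exception as exc:   # preserve partial results with an error manifest
        manifest["status"] = "error"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
        (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    _write_summary(report, outdir / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["oscicoupler run summary", "======================="]
    for name, b in report.get("bands", {}).items():
        lines.append(f"band[{name}]: centre {b['centre_hz']:.2f} Hz "
                     f"({b['low_hz']:.2f}-{b['high_hz']:.2f}), chi {b['chi']:.2f}")
    for name, lat in report.get("hg_latencies", {}).items():
        lines.append(f"HG[{name}]: onset {lat['onset_ms']} ms, "
                     f"peaks {lat['peaks_ms']}")
    for pair, r in report.get("plv", {}).items():
        lines.append(f"PLV[{pair}]: {r['plv']} diff {r['difference']} p {r['p']}")
    if "z_pac" in report:
        lines.append(f"z-PAC: {report['z_pac']}")
    if "lag_pac" in report:
        lines.append(f"lag-PAC peaks: {report['lag_pac']}")
    if "psi" in report:
        lines.append(f"PSI: {report['psi']}")
    if "granger" in report:
        lines.append(f"Granger: {report['granger']}")
    lines.append(f"direction calls: {report.get('direction_calls')}")
    path.write_text("\n".join(lines) + "\n")


__all__ = [
    "PipelineConfig",
    "save_recording",
    "load_recording",
    "load_events",
    "select_pairs",
    "select_best_pair",
    "synthesize",
    "run_pipeline",
]
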