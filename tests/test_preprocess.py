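"""Signal conditioning: filtering, line-noise regression, re-referencing,
epoching, saccade detection."""

import numpy as np
import pytest

import oscicoupler as oc
from oscicoupler import preprocess as pp
from oscicoupler import spectral
from oscicoupler.containers import ChannelInfo, Recording
from oscicoupler.synthdata import simulate_eog

from conftest import make_session

FS = 1000.0


def sine_recording(freqs_amps, fs=FS, dur=10.0, n_ch=1):
    t = np.arange(int(dur * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(x, (n_ch, 1))
    chans = [ChannelInfo(f"ch{i}", "amygdala-BLA", "A", i + 1)
             for i in range(n_ch)]
    return Recording(data, fs, chans)


class TestBandpassFir:
    def test_passband_identity_and_zero_phase(self):
        rec = sine_recording([(6.0, 1.0)])
        out = pp.bandpass_fir(rec, 4.0, 8.0)
        y = out.data[0][2000:-2000]
        x = rec.data[0][2000:-2000]
        assert np.abs(y).max() == pytest.approx(1.0, rel=0.05)
        # zero phase: cross-correlation peak at lag 0
        lags = np.arange(-50, 51)
        xc = [np.dot(y[50 + k:len(y) - 50 + k], x[50:-50]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_stopband_attenuation(self):
        rec = sine_recording([(30.0, 1.0)])
        taps = pp.design_bandpass_fir(FS, 4.0, 8.0, n_samples=rec.n_samples)
        # oracle: two-pass response magnitude at 30 Hz from the design
        from scipy.signal import freqz
        w, h = freqz(taps, worN=[30.0], fs=FS)
        predicted_rms = (np.abs(h[0]) ** 2) / np.sqrt(2)
        out = pp.bandpass_fir(rec, 4.0, 8.0).data[0][2000:-2000]
        rms = np.sqrt(np.mean(out ** 2))
        assert rms < 0.05
        assert rms == pytest.approx(predicted_rms, abs=0.01)

    def test_band_edges_validated(self):
        rec = sine_recording([(6.0, 1.0)])
        with pytest.raises(ValueError):
            pp.bandpass_fir(rec, 8.0, 4.0)
        with pytest.raises(ValueError):
            pp.bandpass_fir(rec, 4.0, 600.0)

    def test_passband_idempotence(self):
        """Filtering twice changes pass-band (4-8 Hz) RMS by < 1%."""
        rng = np.random.default_rng(0)
        rec = sine_recording([(6.0, 1.0)], dur=30.0)
        rec.data[0] += 0.5 * rng.standard_normal(rec.n_samples)
        once = pp.bandpass_fir(rec, 4.0, 8.0)
        twice = pp.bandpass_fir(once, 4.0, 8.0)

        def inband_rms(x):
            psd = spectral.welch_psd(x, FS, window_s=2.0)
            m = (psd.freqs >= 4.0) & (psd.freqs <= 8.0)
            return np.sqrt(np.trapezoid(psd.power[m], psd.freqs[m]))

        assert inband_rms(twice.data[0]) == pytest.approx(
            inband_rms(once.data[0]), rel=0.01)

    def test_broadband_conditioning_chain(self):
        """0.1-350 Hz conditioning then down-sampling to the analysis rate."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, int(10 * 5000)))
        rec = Recording(data, 5000.0,
                        [ChannelInfo("a", "amygdala-BLA", "A", 1),
                         ChannelInfo("b", "hippocampus-CA1", "H", 1)])
        out = pp.condition_broadband(rec, 0.1, 350.0, target_fs=2000.0)
        assert out.fs == 2000.0
        assert out.n_samples == int(10 * 2000)
        assert not np.isnan(out.data).any()


class TestRemoveLineNoise:
    def test_pure_line_removed(self):
        rec = sine_recording([(60.0, 1.0)], dur=20.0)
        out = pp.remove_line_noise(rec, 60.0, 1)
        assert np.sqrt(np.mean(out.data[0] ** 2)) < 0.01

    def test_neighbouring_band_preserved(self):
        rec = sine_recording([(6.0, 1.0), (60.0, 1.0)], dur=20.0)
        out = pp.remove_line_noise(rec, 60.0, 1)
        # 6 Hz component compared before/after with the same band measure
        ref = spectral.analytic_signal(
            rec.data[0], FS, 4, 8).amplitude[2000:-2000].mean()
        amp6 = spectral.analytic_signal(
            out.data[0], FS, 4, 8).amplitude[2000:-2000].mean()
        assert amp6 == pytest.approx(ref, rel=0.01)

    def test_broadband_psd_barely_changed(self, rng):
        data = rng.standard_normal((1, int(60 * FS)))
        rec = Recording(data, FS, [ChannelInfo("a", "amygdala-BLA", "A", 1)])
        out = pp.remove_line_noise(rec, 60.0, 3)
        p_in = spectral.welch_psd(rec.data[0], FS)
        p_out = spectral.welch_psd(out.data[0], FS)
        keep = np.ones_like(p_in.freqs, dtype=bool)
        for k in (60, 120, 180):
            keep &= np.abs(p_in.freqs - k) > 1.0
        keep &= (p_in.freqs > 1)
        rel = np.abs(p_out.power[keep].sum() - p_in.power[keep].sum())
        assert rel / p_in.power[keep].sum() < 0.01


class TestRereference:
    @staticmethod
    def shaft(datas, fs=FS):
        chans = []
        for i in range(len(datas) - 1):
            chans.append(ChannelInfo(f"g{i}", "amygdala-BLA", "A", i + 1))
        chans.append(ChannelInfo("wm", "white-matter", "A", len(datas)))
        return Recording(np.vstack(datas), fs, chans)

    def test_identical_signals_cancel(self):
        x = np.sin(np.arange(1000) * 0.01)
        rec = self.shaft([x, x])
        out = pp.rereference_white_matter(rec)
        assert np.allclose(out.get("g0"), 0.0)

    def test_common_line_noise_suppressed(self, rng):
        t = np.arange(int(30 * FS)) / FS
        line = np.sin(2 * np.pi * 60 * t)
        g = rng.standard_normal(t.size) * 0.1 + line
        w = rng.standard_normal(t.size) * 0.1 + line
        out = pp.rereference_white_matter(self.shaft([g, w]))
        p_before = spectral.welch_psd(g, FS)
        p_after = spectral.welch_psd(out.get("g0"), FS)
        i60 = np.argmin(np.abs(p_before.freqs - 60))
        drop_db = 10 * np.log10(p_before.power[i60] / p_after.power[i60])
        assert drop_db > 20

    def test_nearest_reference_on_shaft(self, rng):
        datas = [rng.standard_normal(500) for _ in range(4)]
        rec = Recording(np.vstack(datas), FS, [
            ChannelInfo("g0", "amygdala-BLA", "A", 1),
            ChannelInfo("g1", "amygdala-BLA", "A", 2),
            ChannelInfo("g2", "amygdala-BLA", "A", 3),
            ChannelInfo("wm", "white-matter", "A", 4)])
        out = pp.rereference_white_matter(rec)
        assert out.annotations["reference"] == {
            "g0": "wm", "g1": "wm", "g2": "wm"}

    def test_adding_reference_back_reconstructs(self, rng):
        datas = [rng.standard_normal(500), rng.standard_normal(500)]
        rec = self.shaft(datas)
        out = pp.rereference_white_matter(rec)
        assert np.allclose(out.get("g0") + rec.get("wm"), rec.get("g0"))

    def test_no_white_matter_is_error(self):
        rec = sine_recording([(6.0, 1.0)])
        with pytest.raises(ValueError):
            pp.rereference_white_matter(rec)


class TestEpoch:
    def test_one_trial_per_clip(self, small_schedule):
        rec, ev, _ = make_session(1, schedule=small_schedule, fs=500.0)
        eps = pp.epoch(rec, ev)
        assert eps.n_trials == len(ev)

    def test_full_default_schedule_has_141_trials(self):
        ev = oc.make_task_schedule(oc.TaskScheduleParams())
        n = int((ev.onset_s.iloc[-1] + ev.duration_s.iloc[-1]) * 100)
        rec = Recording(np.zeros((1, n)), 100.0,
                        [ChannelInfo("a", "amygdala-BLA", "A", 1)])
        eps = pp.epoch(rec, ev, window=(-0.1, 0.1))
        assert eps.n_trials == 141

    def test_empty_events(self):
        import pandas as pd
        rec = sine_recording([(6.0, 1.0)])
        empty = pd.DataFrame(columns=["onset_s", "duration_s", "condition", "block"])
        eps = pp.epoch(rec, empty)
        assert eps.n_trials == 0

    def test_incomplete_trial_flagged(self):
        import pandas as pd
        rec = sine_recording([(6.0, 1.0)], dur=5.0)
        ev = pd.DataFrame([[0.2, 1.0, "neutral", 0]],
                          columns=["onset_s", "duration_s", "condition", "block"])
        eps = pp.epoch(rec, ev, window=(-0.5, 1.5))
        assert eps.bad[0]

    def test_samples_conserved(self, rng):
        import pandas as pd
        rec = sine_recording([(6.0, 1.0)], dur=5.0)
        rec.data[0] = rng.standard_normal(rec.n_samples)
        ev = pd.DataFrame([[2.0, 1.0, "neutral", 0]],
                          columns=["onset_s", "duration_s", "condition", "block"])
        eps = pp.epoch(rec, ev, window=(-0.5, 1.5))
        i0 = int(2.0 * FS) + int(-0.5 * FS)
        assert np.array_equal(eps.data[0, 0], rec.data[0, i0:i0 + 2000])


class TestSaccades:
    def test_constant_gaze_no_events(self):
        rec = Recording(np.ones((2, 5000)), 500.0,
                        [ChannelInfo("h", "EOG"), ChannelInfo("v", "EOG")])
        res = pp.detect_saccades(rec)
        assert res.sample.size == 0

    def test_recovery_from_simulated_eog(self, small_schedule):
        rec = simulate_eog(small_schedule, saccade_rate_hz=0.4, fs=500.0, seed=9)
        truth = np.array(rec.annotations["saccade_times_s"])
        assert truth.size >= 30
        det = pp.detect_saccades(rec)
        hits = sum(np.min(np.abs(det.time_s - t)) <= 0.02 for t in truth)
        assert hits / truth.size >= 0.9

    def test_min_spacing_merges_close_steps(self):
        fs = 500.0
        n = int(10 * fs)
        x = np.zeros(n)
        big = int(5 * fs)
        x[big:] += 10.0          # large step
        x[big + int(0.1 * fs):] += 5.0   # smaller step 100 ms later
        rec = Recording(np.vstack([x, np.zeros(n)]), fs,
                        [ChannelInfo("h", "EOG"), ChannelInfo("v", "EOG")])
        res = pp.detect_saccades(rec)
        assert res.sample.size == 1
        assert abs(res.sample[0] - big) <= 2


class TestPerisaccadicHg:
    def test_null_calibration(self, small_schedule):
        """LFP independent of saccades: ~5% of time points significant."""
        fracs = []
        for seed in range(10):
            rec, ev, _ = make_session(400 + seed, schedule=small_schedule,
                                      fs=500.0, evoked_hg_amp_aversive=0.0)
            eog = simulate_eog(small_schedule, 1.0, fs=500.0, seed=seed)
            sac = pp.detect_saccades(eog)
            res = pp.perisaccadic_hg(rec.pick(["amy1", "hpc1"]), sac, ev)
            if res["p"] is not None:
                fracs.append(np.mean(res["p"] < 0.05))
        assert 0.0 <= np.mean(fracs) < 0.15

    def test_zero_saccades_warns_empty(self, small_schedule):
        rec, ev, _ = make_session(3, schedule=small_schedule, fs=500.0)
        empty = pp.SaccadeEvents(np.array([], int), np.array([]),
                                 np.array([]), np.inf)
        with pytest.warns(UserWarning):
            res = pp.perisaccadic_hg(rec.pick(["amy1", "hpc1"]), empty, ev)
        assert res["traces"] == {}

    def test_injected_burst_detected(self, small_schedule):
        """HG burst at each saccade in one condition only is detected."""
        fs = 500.0
        rec, ev, _ = make_session(5, schedule=small_schedule, fs=fs,
                                  evoked_hg_amp_aversive=0.0)
        eog = simulate_eog(small_schedule, 1.0, fs=fs, seed=4)
        sac = pp.detect_saccades(eog)
        from oscicoupler.synthdata import condition_per_sample
        lab = condition_per_sample(ev, rec.n_samples, fs)
        data = rec.data.copy()
        t = np.arange(int(0.1 * fs)) / fs
        burst = np.sin(2 * np.pi * 120 * t) * 3.0
        for s in sac.sample:
            if s + burst.size < rec.n_samples and lab[s] == "aversive":
                data[0, s:s + burst.size] += burst
        rec2 = rec.copy_with(data=data)
        res = pp.perisaccadic_hg(rec2.pick(["amy1", "hpc1"]), sac, ev)
        post = res["times"] >= 0
        assert res["p"] is not None
        assert (res["p"][post] < 0.01).any()
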