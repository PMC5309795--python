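"""PLV, PAC, z-PAC and lag-PAC, with independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscicoupler import coupling, spectral
from oscicoupler.containers import AVERSIVE, NEUTRAL
from oscicoupler.synthdata import condition_per_sample

from conftest import make_session

FS = 1000.0


# ------------------------------------------------------- brute-force oracles

def plv_loop(phase_i, phase_j):
    """Single-loop PLV over one window."""
    acc = 0.0 + 0.0j
    for a, b in zip(phase_i, phase_j):
        acc += complex(np.cos(a - b), np.sin(a - b))
    return abs(acc / len(phase_i))


def rho_loop(phase, amp):
    """Single-loop circular-linear correlation from the three Pearson r."""
    n = len(phase)
    c = [np.cos(p) for p in phase]
    s = [np.sin(p) for p in phase]

    def pearson(x, y):
        mx = sum(x) / n
        my = sum(y) / n
        num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        dx = np.sqrt(sum((xi - mx) ** 2 for xi in x))
        dy = np.sqrt(sum((yi - my) ** 2 for yi in y))
        return num / (dx * dy)

    r_ca = pearson(c, list(amp))
    r_sa = pearson(s, list(amp))
    r_cs = pearson(s, c)
    return np.sqrt((r_ca ** 2 + r_sa ** 2 - 2 * r_ca * r_sa * r_cs)
                   / (1 - r_cs ** 2))


class TestPlv:
    def test_constant_phase_offset_gives_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, int(5 * FS))
        shifted = np.angle(np.exp(1j * (phi + 1.234)))
        assert coupling.plv(phi, shifted, FS) == pytest.approx(1.0)

    def test_identical_series_every_window_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, int(5 * FS))
        pv = coupling.windowed_plv(phi, phi, FS)
        assert np.allclose(pv, 1.0)

    def test_rayleigh_bias_matches_brute_force_expectation(self):
        """Window PLV of independent phases matches the Monte-Carlo mean
        of the Rayleigh resultant and decreases with window length."""
        r = np.random.default_rng(0)
        for n in (100, 1000):
            expect = np.mean([
                np.abs(np.mean(np.exp(1j * r.uniform(-np.pi, np.pi, n))))
                for _ in range(2000)])
            got = np.mean([
                coupling.plv(r.uniform(-np.pi, np.pi, n),
                             r.uniform(-np.pi, np.pi, n), n)
                for _ in range(200)])
            assert got == pytest.approx(expect, rel=0.15)
        # bias shrinks roughly as 1/sqrt(n)
        assert coupling.plv(r.uniform(-np.pi, np.pi, 10000),
                            r.uniform(-np.pi, np.pi, 10000), 10000) < 0.05

    def test_matches_loop_oracle(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 1000)
        psi = rng.uniform(-np.pi, np.pi, 1000)
        assert coupling.plv(phi, psi, 1000) == pytest.approx(
            plv_loop(phi, psi), abs=1e-10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            coupling.plv(np.zeros(10), np.zeros(10), FS)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-np.pi, np.pi))
    def test_common_offset_invariance_and_range(self, seed, offset):
        r = np.random.default_rng(seed)
        phi = r.uniform(-np.pi, np.pi, 2000)
        psi = r.uniform(-np.pi, np.pi, 2000)
        base = coupling.plv(phi, psi, 1000)
        moved = coupling.plv(np.angle(np.exp(1j * (phi + offset))),
                             np.angle(np.exp(1j * (psi + offset))), 1000)
        assert 0.0 <= base <= 1.0
        assert moved == pytest.approx(base, abs=1e-9)


class TestPac:
    def test_perfect_dependence_gives_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 5000)
        assert coupling.pac_circular_linear(phi, np.cos(phi)).rho \
            == pytest.approx(1.0, abs=1e-9)

    def test_independent_amplitude_below_permutation_null(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        obs = coupling.pac_circular_linear(phi, amp).rho
        null = [coupling.pac_circular_linear(rng.permutation(phi), amp).rho
                for _ in range(200)]
        assert obs < np.percentile(null, 95)

    def test_matches_loop_oracle(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 1000)
        amp = 1 + 0.5 * np.cos(phi - np.pi) + 0.1 * rng.standard_normal(1000)
        res = coupling.pac_circular_linear(phi, amp)
        assert res.rho == pytest.approx(rho_loop(phi, amp), abs=1e-12)

    def test_zero_variance_amplitude_flagged(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 1000)
        res = coupling.pac_circular_linear(phi, np.full(1000, 2.0))
        assert res.rho == 0.0
        assert res.degenerate

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_affine_invariance_of_amplitude(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        phi = r.uniform(-np.pi, np.pi, 1500)
        amp = r.gamma(2.0, 1.0, 1500)
        base = coupling.pac_circular_linear(phi, amp).rho
        moved = coupling.pac_circular_linear(phi, scale * amp + shift).rho
        assert 0.0 <= base <= 1.0
        assert moved == pytest.approx(base, abs=1e-9)


class TestPlvContrast:
    def test_simulated_coupling_contrast_recovered(self, full_session):
        rec, ev, truth = full_session
        fs = rec.fs
        ph_a = spectral.analytic_signal(rec.get("amy1"), fs, 4, 8).phase
        ph_h = spectral.analytic_signal(rec.get("hpc1"), fs, 4, 8).phase
        labels = coupling.window_conditions(ev, rec.n_samples, fs)
        res = coupling.plv_contrast(ph_a, ph_h, labels, fs, n_perm=200, seed=2)
        assert res.passed_step1
        assert res.difference > 0
        assert res.p_value < 0.05

    def test_identical_conditions_zero_difference(self, rng):
        phi = rng.uniform(-np.pi, np.pi, int(20 * FS))
        psi = np.angle(np.exp(1j * (phi + 0.5)))   # fully locked pair
        labels = np.array([AVERSIVE, NEUTRAL] * 10, dtype=object)
        res = coupling.plv_contrast(phi, psi, labels, FS, n_perm=100, seed=0)
        assert res.passed_step1
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_label_shuffle_type_one_error(self):
        """Condition labels assigned at random: ~5% false positives."""
        hits = 0
        runs = 40
        for seed in range(runs):
            r = np.random.default_rng(seed)
            n = int(30 * FS)
            common = r.uniform(-np.pi, np.pi, n)
            noise = 0.8
            phi = np.angle(np.exp(1j * (common + noise * r.standard_normal(n))))
            psi = np.angle(np.exp(1j * (common + noise * r.standard_normal(n))))
            labels = np.array([AVERSIVE, NEUTRAL] * 15, dtype=object)
            r.shuffle(labels)
            res = coupling.plv_contrast(phi, psi, labels, FS, n_perm=100,
                                        seed=seed)
            if res.passed_step1 and res.p_value is not None:
                hits += res.p_value < 0.05
        assert hits / runs < 0.2


class TestPlvSpectrum:
    def test_injected_six_hz_coupling_peaks_in_theta(self, full_session):
        rec, ev, truth = full_session
        fs = rec.fs
        labels = coupling.window_conditions(ev, rec.n_samples, fs)
        out = coupling.plv_spectrum(rec.get("amy1"), rec.get("hpc1"), fs,
                                    labels, f_min=2.0, f_max=20.0)
        peak = out["freqs"][np.argmax(out["z"])]
        assert 4.0 <= peak <= 8.0

    def test_spline_interpolates_bin_values(self, full_session):
        rec, ev, truth = full_session
        fs = rec.fs
        labels = coupling.window_conditions(ev, rec.n_samples, fs)
        out = coupling.plv_spectrum(rec.get("amy1"), rec.get("hpc1"), fs,
                                    labels, f_min=2.0, f_max=10.0)
        at_centres = out["spline"](out["freqs"])
        assert np.allclose(at_centres, out["z"], atol=1e-8)


class TestZPac:
    def _session_arrays(self, seed, **kw):
        rec, ev, truth = make_session(seed, fs=500.0,
                                      evoked_hg_amp_aversive=0.0, **kw)
        fs = rec.fs
        ph = spectral.analytic_signal(rec.get("amy1"), fs, 4, 8).phase
        amp = spectral.analytic_signal(rec.get("hpc1"), fs, 70, 180).amplitude
        segs, labels = coupling.segment_bounds_from_events(ev, fs, rec.n_samples)
        return ph, amp, segs, labels

    def test_aversive_only_coupling_detected(self):
        hits = 0
        for seed in range(10):
            ph, amp, segs, labels = self._session_arrays(
                600 + seed, modulation_depth_aversive=0.6,
                modulation_depth_neutral=0.0)
            z = coupling.z_pac(ph, amp, segs, labels, n_perm=200, seed=seed)
            hits += z["z"] > 2.33
        assert hits >= 9

    def test_condition_independent_coupling_null(self):
        zs = []
        for seed in range(20):
            ph, amp, segs, labels = self._session_arrays(
                700 + seed, modulation_depth_aversive=0.5,
                modulation_depth_neutral=0.5)
            zs.append(coupling.z_pac(ph, amp, segs, labels, n_perm=100,
                                     seed=seed)["z"])
        assert abs(np.mean(zs)) < 0.5

    def test_comodulogram_asymmetry(self):
        """Amygdala-phase to hippocampus-amplitude cell is significant; the
        reverse-direction comodulogram is not."""
        rec, ev, truth = make_session(801, fs=1000.0,
                                      evoked_hg_amp_aversive=0.0,
                                      modulation_depth_aversive=0.6,
                                      modulation_depth_neutral=0.0)
        fs = rec.fs
        segs, labels = coupling.segment_bounds_from_events(ev, fs, rec.n_samples)
        fwd = coupling.z_pac_comodulogram(
            rec.get("amy1"), rec.get("hpc1"), fs, segs, labels,
            phase_range=(4.0, 9.0), amp_range=(70.0, 140.0),
            n_perm=100, seed=1)
        rev = coupling.z_pac_comodulogram(
            rec.get("hpc1"), rec.get("amy1"), fs, segs, labels,
            phase_range=(4.0, 9.0), amp_range=(70.0, 140.0),
            n_perm=100, seed=2)
        i = np.argmin(np.abs(fwd["phase_freqs"] - truth.f_low_driver_hz))
        j = np.argmin(np.abs(fwd["amp_freqs"] - truth.f_gamma_receiver_hz))
        assert fwd["z"][i, j] > 2.33
        assert rev["z"].max() < fwd["z"][i, j]


class TestLagPac:
    def test_zero_lag_construction_peaks_at_zero(self):
        rec, ev, truth = make_session(900, fs=500.0, conduction_lag_ms=0.0,
                                      evoked_hg_amp_aversive=0.0)
        fs = rec.fs
        ph = spectral.analytic_signal(rec.get("amy1"), fs, 4, 8).phase
        amp = spectral.analytic_signal(rec.get("hpc1"), fs, 70, 180).amplitude
        lab = condition_per_sample(ev, rec.n_samples, fs)
        prof = coupling.lag_pac(ph, amp, fs, sample_mask=(lab == AVERSIVE))
        assert abs(prof.peak_lag_ms) <= 10.0

    def test_uncoupled_signals_below_null(self, rng):
        phi = rng.uniform(-np.pi, np.pi, int(30 * FS))
        amp = rng.gamma(2.0, 1.0, int(30 * FS))
        prof = coupling.lag_pac(phi, amp, FS)
        null = [coupling.pac_circular_linear(rng.permutation(phi), amp).rho
                for _ in range(200)]
        assert prof.rho.max() < np.percentile(null, 99) * 2.0

    def test_lag_grid_symmetric(self, rng):
        phi = rng.uniform(-np.pi, np.pi, int(10 * FS))
        amp = rng.gamma(2.0, 1.0, int(10 * FS))
        prof = coupling.lag_pac(phi, amp, FS)
        assert np.allclose(prof.lags_ms, -prof.lags_ms[::-1])
        assert prof.lags_ms[0] == -200.0 and prof.lags_ms[-1] == 200.0
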