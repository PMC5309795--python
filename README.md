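# oscicoupler

Oscillatory-coupling analysis for two-region intracranial LFP recordings,
built for the question of *directed* interaction between the amygdala and the
hippocampus during emotional-stimulus processing: does a slow (theta/alpha)
rhythm in one structure entrain fast (high-gamma, 70–180 Hz) activity in the
other, and in which direction?

The package is aimed at electrophysiologists analysing depth-electrode
recordings from block-design tasks (here: alternating blocks of neutral
landscape and aversive fearful-face movie clips), and at methodologists who
want every estimator in that chain exercisable against simulations with
known ground truth.

## What it computes

Given a continuous multichannel recording, an events table and channel
region labels, the pipeline reproduces a complete coupling analysis:

* **Preprocessing** — zero-phase least-squares FIR filtering, regression
  removal of 60 Hz noise and harmonics, re-referencing to the nearest
  white-matter contact, epoching (−0.5 to 1.5 s around clip onsets), and
  velocity-threshold saccade detection from EOG.
* **Spectral band selection** — Welch PSD, 1/f (power-law, P ∝ f^(−χ))
  slope fit, and a subject-specific low-frequency band centred on the point
  farthest above the fit (4 Hz bandwidth); an adaptive filter bank
  (centres spaced by 10%, bandwidth ±30%) with Hilbert analytic
  amplitude a_x[n] and phase φ_x[n].
* **Event-locked high gamma** — within-trial z-scored HG amplitude,
  cluster-mass permutation statistics between conditions, onset/offset and
  peak latencies.
* **Phase-locking value** — PLV = |⟨e^{i(φ_i − φ_j)}⟩| over 1-s windows,
  with the two-step permutation significance scheme and PLV difference
  spectra (1–30 Hz, quintic-spline smoothed).
* **Phase–amplitude coupling** — circular–linear correlation
  ρ = √((r_ca² + r_sa² − 2 r_ca r_sa r_cs)/(1 − r_cs²)), its permutation
  z-score between conditions (z-PAC), comodulograms, and PAC as a function
  of time lag (±200 ms, 10 ms steps; negative lag = modulator leads).
* **Directionality** — phase slope index
  Ψ = Im Σ C̃*(f) C̃(f + δf) on (modulating phase signal, modulated HG
  envelope) pairs over sliding windows, and Geweke spectral Granger
  causality from a bivariate AR fit (AIC order selection) with clip-swap
  and condition-flip permutation nulls.

Because clinical recordings of this kind are not freely shareable, the
`synthdata` module is a first-class component: it generates a full
task-structured session (9 neutral / 8 aversive blocks of ~24 s, 70 + 71
clips of 2.8 ± 1.3 s, 0.5 s blank) over a 1/f background, with a stochastic
narrowband driver rhythm whose lagged phase entrains the receiver's gamma
amplitude at known, condition-dependent depth — so every downstream
estimator can be validated by parameter recovery. See `docs/methods.md` for
the full model.

## Worked example

```python
import oscicoupler as oc
from oscicoupler import spectral, coupling

events = oc.make_task_schedule(oc.TaskScheduleParams(seed=0))
truth = oc.CouplingGroundTruth()          # 6 Hz driver, 100 Hz gamma, 15 ms lag
rec = oc.simulate_lfp(events, truth, fs=1000.0, seed=0)

psd = spectral.welch_psd(rec.get("amy1"), rec.fs)
band = spectral.select_subject_band(psd, spectral.fit_powerlaw(psd))
print(f"subject band: {band.low_hz:.2f}-{band.high_hz:.2f} Hz "
      f"(centre {band.centre_hz:.2f} Hz)")

phase = spectral.analytic_signal(rec.get("amy1"), rec.fs,
                                 band.low_hz, band.high_hz).phase
amp = spectral.analytic_signal(rec.get("hpc1"), rec.fs, 70, 180).amplitude
segs, labels = coupling.segment_bounds_from_events(events, rec.fs, rec.n_samples)
out = coupling.z_pac(phase, amp, segs, labels, n_perm=500, seed=1)
print(f"PAC rho: aversive {out['rho_by_condition']['aversive']:.3f}, "
      f"neutral {out['rho_by_condition']['neutral']:.3f}")
print(f"z-PAC (aversive - neutral): {out['z']:.2f}  (p = {out['p']:.4f})")
```

prints

```
subject band: 4.00-8.00 Hz (centre 6.00 Hz)
PAC rho: aversive 0.432, neutral 0.398
z-PAC (aversive - neutral): 2.96  (p = 0.0020)
```

The band selector recovers the driver rhythm (6 Hz) from the PSD alone; the
hippocampal gamma amplitude is coupled to the amygdala theta phase in both
conditions (ρ ≈ 0.4) but more strongly during aversive blocks, and the
permutation z-score of that difference is significant. Continuing with
`coupling.lag_pac` on the aversive samples peaks at −10 ms — the grid cell
adjacent to the generator's 15 ms conduction delay, with the negative sign
meaning the amygdala phase leads.

The whole chain, from synthesis to direction calls, is one command:

```bash
oscicoupler run --config cfg.yaml --out results/
oscicoupler report --results results/
```

which writes `report.json`, TSV matrices, a run manifest with all seeds and
parameters, and a plain-text summary (band centres, HG latencies, PLV
contrasts, z-PAC, lag profiles, PSI and Granger direction calls).
`oscicoupler synth` and `oscicoupler analyze` expose the two halves
separately; recordings are interchanged as `.npy` + JSON sidecar + events
TSV, and EDF input is read via mne.

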