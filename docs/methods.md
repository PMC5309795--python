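# Methods

`oscicoupler` implements a complete oscillatory-coupling analysis chain for
two-region intracranial LFP (amygdala and hippocampus depth recordings during
an alternating-block emotional-stimulus task), together with a synthetic
session generator whose coupling parameters are known exactly. This note
documents the models, conventions, parameter choices and known limitations.

## The synthetic session

### Task schedule

The default schedule reproduces the study conditions: 9 neutral (landscape)
blocks alternating with 8 aversive (fearful-face) blocks of 24 s each,
preceded by a 0.5 s blank screen. 70 neutral and 71 aversive clips
(duration 2.8 ± 1.3 s, truncated normal) tile the blocks contiguously. The
paper-style constraint that clips are "shown continuously without breaks" is
enforced by drawing clip durations and rescaling them so each block is filled
exactly. Whether the session starts with a neutral or aversive block is not
constrained by the task description; the generator defaults to neutral-first
and exposes `first_condition`.

### Signal model

Each channel is a sum of:

* **1/f background** — frequency-domain shaped Gaussian noise with amplitude
  ∝ f^(−χ/2), so the PSD falls as f^(−χ); default χ = 2, unit SD.
* **Low-frequency oscillation** — a *stochastic* narrowband process (Gaussian
  spectral profile, default bandwidth 2 Hz) at 6 Hz on the driver (amygdala)
  and 6.5 Hz on the receiver (hippocampus), SD = `osc_amp` (default 1).
  A stochastic rather than sinusoidal rhythm matters in three ways: a
  sinusoid is perfectly predictable from its own past (Granger causality from
  a sinusoidal driver would be identically zero), the lag-PAC profile of a
  sinusoid is periodic rather than unimodal, and the analytic phase of a
  narrowband process is what the estimation chain actually measures.
* **Directed low-frequency coupling** — the lagged driver oscillation is
  mixed into the receiver's low-frequency component with weight w per
  condition (default: equal to the PAC modulation depth). This produces the
  inter-regional theta/alpha phase synchrony that PLV measures and the
  directed low-frequency influence that PSI and Granger detect.
* **Gamma carrier** — a stochastic narrowband process at 100 Hz (bandwidth
  40 Hz) on both channels, so the high-gamma amplitude fluctuates on its own
  as real population activity does; with a deterministic carrier the
  receiver's envelope would be an exact function of the driver phase and PAC
  ρ would saturate near 1. On the receiver the carrier is multiplied by
  `base + depth·(1 + cos φ_d(t − lag))/2` where
  φ_d is the driver's analytic low-frequency phase, `lag` is the conduction
  delay (default 15 ms, positive = driver leads) and `depth` takes the
  block's condition value (0 during the blank). The driver's gamma amplitude
  is constant, so phase→amplitude coupling exists only driver→receiver
  ("directional purity"); reverse-direction PAC estimates are null by
  construction.
* **Evoked high gamma** — a half-cosine rise (100 ms) to a plateau (400 ms)
  with a half-cosine fall (200 ms), added to the gamma envelope starting
  `hg_onset_ms` after each clip onset (defaults 120 ms amygdala, 240 ms
  hippocampus), with condition-specific amplitude (default 0.5, aversive
  only). Evoked transients add phase-independent amplitude variance and
  therefore *dilute* correlation-based PAC; the default amplitude is chosen
  so the aversive > neutral PAC ordering survives the dilution, as it does
  in the data this emulates.
* **Optional 60 Hz line noise** with 1/k harmonics, and optional EOG channels
  (slow drift plus step-like saccade transients at Poisson times with a
  200 ms refractory period).

Default modulation depths are 0.6 (aversive) and 0.3 (neutral): coupling
present in both conditions but stronger for aversive stimuli, which is the
qualitative structure the analyses are designed to detect, and strong enough
in the neutral condition that within-condition PLV clears its own
permutation threshold, as observed in this kind of data.

### What the generator does not emulate

No epileptiform transients, no volume conduction or shared reference
artifacts beyond optional common line noise, no non-stationarity of the
background across the session, no gaze-position structure beyond step
saccades, and only one contact per grey-matter region by default. Passing
tests on these simulations therefore validates the *estimators* (bias, sign
conventions, calibration, parameter recovery), not robustness to every
pathology of clinical recordings.

## Signal conditioning

* **Band-pass filtering**: two-way (forward–backward, zero-phase)
  least-squares FIR, length ⌈4·fs/low-edge⌉ taps (4 cycles of the low edge),
  15% transition bands, implemented with FFT convolution and reflect padding.
  The filter is normalized to exactly unit gain at the band centre, since the
  least-squares ripple otherwise leaves a ~1% dip that compounds over the two
  passes.
* **Acquisition-style conditioning** (0.1–350 Hz, then down-sampling):
  the 0.1 Hz edge would require an impractically long FIR under the cycles
  rule, so the high-pass side is a zero-phase 4th-order Butterworth and only
  the low-pass side is FIR (Hamming). Down-sampling uses polyphase
  resampling with its default anti-alias design.
* **Line noise**: sine/cosine regressors at 60 Hz and harmonics fitted by
  least squares over 10 s segments with 50% overlap, blended with a Hann
  taper and subtracted.
* **Re-referencing**: each grey-matter contact minus the nearest (by contact
  index) white-matter contact on its shaft; the reference map is recorded in
  the annotations, so adding the reference back reconstructs the input.
* **Saccades**: velocity = first difference of the Euclidean distance between
  successive (x, y) EOG samples; events at local velocity peaks above the
  session-wide 99th percentile, with a 200 ms minimum spacing (larger peak
  wins on conflict).

## Spectral band selection

Welch PSD (1 s Hann windows, 50% overlap). Two slope parameterizations are
fitted over a configurable range (default 2–80 Hz): the semi-log regression
coefficient β of log-power on frequency, and the power-law exponent χ from
the log-log fit. A power-law is linear only in log-log space, so band
selection measures distances from the log-log fit by default; both fits are
always reported and the choice is recorded on the `SlopeFit`. The
subject-specific band is centred on the frequency with the maximal positive
distance of log-PSD above the fitted curve within a 4–12 Hz search range
(theta/alpha, where event-related low-frequency peaks occur), with a fixed
4 Hz bandwidth; a spectrum with no point above its fit falls back to the
range midpoint with a flag.

When the goal is to *recover* the background exponent χ of a simulation, the
fit should be restricted to a background-dominated range: an injected
theta/alpha peak inside the fit range inflates the log-log slope by several
tenths, and the stochastic gamma band's lower shoulder flattens it above
~40 Hz — properties of the data, not of the estimator (which is unbiased on
pure shaped noise). The package's recovery tests fit 10–30 Hz using 2 s
Welch windows (the longer window sharpens the theta peak's leakage skirt so
it no longer reaches 10 Hz).

The adaptive filter bank spaces centre frequencies by 10% of the current
centre (c, 1.1c, 1.21c, …) with bandwidth 0.6·c (±30%), so a 10 Hz bin is
followed by an 11 Hz bin with a 6 Hz bandwidth; consecutive bins overlap at
every scale. Phase and amplitude come from the Hilbert analytic signal of
the band-passed trace; phase uses the cosine convention (0 = peak,
±π = trough).

## Statistics

* **Cluster-mass permutation test**: condition labels are shuffled at the
  trial level (1,000 permutations by default); per-timepoint permutation-t
  scores are the observed (or null) mean difference standardized by the null
  ensemble mean and SD; contiguous runs beyond the two-tailed 5% Gaussian
  threshold form clusters (positive and negative separately); corrected p is
  the fraction of null maximal |mass| values at least as large. Zero-variance
  timepoints are excluded from cluster formation. The description of
  t-scores "compared to the entire distribution" of null differences is
  implemented as this standardization; it is an interpretation.
* **Onset/offset**: first and last sample inside corrected-significant
  clusters. For evoked-onset readouts the search is restricted to
  post-stimulus samples and positive (condition-1 > condition-2) clusters:
  within-trial z-scoring converts an evoked bump partly into a tonic negative
  offset which would otherwise be read as a pre-stimulus onset.
* **Percentile nulls** use linear interpolation; permutation p-values are
  computed with the (1 + #{null ≥ obs}) / (n_perm + 1) convention.
* **Fisher's z**: arctanh, with |ρ| ≥ 1 clipped to 1 − 1e−12 under a warning.

## Coupling measures

* **PLV** between two wrapped phase series over non-overlapping 1 s windows;
  a condition's PLV is the arithmetic mean of its window PLVs (aggregation
  unstated in the source description; the mean is the simplest unbiased
  choice). Significance is two-step: (1) within each condition the pairing
  between the two channels' windows is permuted and the pair must exceed the
  99th-percentile null in *both* conditions; (2) window condition labels are
  permuted for a two-sided p on the PLV difference. PLV difference spectra
  over the 1–30 Hz filter bank are z-normalized across bins and smoothed
  with an order-5 interpolating spline (bin-centre values unchanged).
* **PAC**: circular–linear correlation
  ρ = √((r_ca² + r_sa² − 2 r_ca r_sa r_cs)/(1 − r_cs²)) with
  r_ca = corr(cos φ, a), r_sa = corr(sin φ, a), r_cs = corr(sin φ, cos φ),
  both circular terms from the *same* modulating phase (the standard
  definition; a subscript variant in the source text is treated as a slip).
  "Phase of high frequency" is read as the analytic amplitude of the high
  frequency band, consistent with the displayed correlations. ρ is computed
  from additive sufficient statistics per clip, so permutation nulls reuse
  per-clip sums instead of rescanning samples.
* **z-PAC**: clips are the exchangeable unit; condition labels are permuted,
  the Fisher-z PAC difference recomputed, and the observed difference
  expressed as a z-score against the null (positive = stronger coupling when
  aversive). The exact two-sided permutation p is returned alongside, and is
  the calibrated 0.05-level decision: the null Δρ_z distribution is
  platykurtic (ρ is a folded magnitude), so ±1.96 on the z-summary
  under-rejects slightly.
* **Lag-PAC**: ρ between φ(t) and a(t − L) on a ±200 ms grid in 10 ms steps;
  a peak at negative L means the amplitude pattern reproduces the phase only
  after a delay — the modulator leads. A 15 ms conduction delay therefore
  peaks at the −10 or −20 ms grid cell.

## Directionality

* **PSI**: from epoch-averaged cross-spectra (Hann taper, zero-padded to the
  requested δf resolution) the complex coherency C(f) is formed and
  Ψ = Im Σ_band conj(C(f))·C(f + δf), summed over a band of *total* width
  8·δf centred at ν — a centre of 8 Hz at δf = 1 Hz spans 4–12 Hz, which
  reconciles the "eight times the frequency resolution" definition with the
  "(β = 4 Hz)" half-width in the source's worked example. Inputs are the
  modulating channel's band-passed signal and the modulated channel's
  high-gamma amplitude envelope. Ψ(x→y) = −Ψ(y→x) exactly. Sliding windows
  (100 ms, 25 ms steps) track the direction over the epoch;
  99.5th-percentile thresholds come from permuting the epoch pairing.
  A single taper per window is used given the 100 ms length.
* **Spectral Granger causality**: epochs are low-pass filtered at 85 Hz and
  down-sampled to 250 Hz upstream; a bivariate VAR is fitted by least squares
  pooled across epoch realizations; the order minimizes AIC over 1–20, with
  all candidate fits conditioned on the same target samples (otherwise the
  per-order likelihoods are not comparable and AIC drifts upward). The
  Geweke frequency-domain measure is computed with the standard
  noise-covariance normalization; unstable fits are refitted at lower order
  with a warning. Two permutation nulls: swapping each clip's channel
  assignment (within-condition significance band, central 99%), and flipping
  clip condition labels (condition contrast, two-sided with 1% per tail —
  resolving the mixed 99%/98% wording as a symmetric 2% total tail mass).

## Pipeline

`run_pipeline` chains synthesis (or a loaded recording), optional line-noise
removal, white-matter re-referencing, epoching (−0.5 to 1.5 s), per-channel
band selection, HG time courses with cluster statistics and latencies, PLV
contrasts over the medial-contact pairs (3 amygdala × 4 hippocampus by rule;
"medial" = lowest contact index), forwarding of the most significant pair to
z-PAC / comodulogram / lag-PAC / PSI / Granger, and a JSON + TSV report with
a manifest recording seeds and parameters. Direction calls require the
forward statistic to be individually significant and to exceed its reverse
counterpart. Recordings are interchanged as `.npy` + JSON sidecar + events
TSV (lossless); EDF input is read through mne.

## Numerical and testing notes

* All randomness flows through explicit `numpy.random.default_rng` seeds;
  identical seeds give bit-identical simulations and permutation nulls.
* Trough detection marks the sample nearest ±π at each phase wrap, robust to
  the per-sample phase step (a fixed small tolerance below −π misses troughs
  once the step exceeds it, e.g. above ~1 Hz at 500 Hz sampling).
* The test suite runs simulations at 500–1000 Hz with 4 + 3 block sessions
  (the full 9 + 8 schedule is used where threshold precision matters, at
  500 Hz), sizes chosen so the estimators operate in the same regime as the
  full-rate defaults while the whole suite remains quick. Calibration checks
  use 200 replicates at 200 permutations; recovery checks use 20 seeds.
* Known limitations: PLV over short windows is biased upward for narrowband
  signals at nearby frequencies (the two-step permutation thresholds account
  for this); the evoked-onset estimate is delayed relative to the true ramp
  start by the significance threshold crossing (~30–60 ms at the default
  effect size), which preserves ordering but is not an unbiased latency
  estimator; Granger on band-limited, noisy shared signals shows small
  spurious reverse-direction values (denoising effect), so dominance, not
  exclusivity, is the direction criterion.
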