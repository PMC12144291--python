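# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `eegtrt`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data model

A session is a 63-channel continuous recording in microvolts at 1000 Hz
against an FCz online reference (the standard 64-channel active-electrode
10-10 cap), with a typed event table (onset in seconds, modality,
condition, 1-based run index, paradigm) and subject/group/occasion
metadata. Electrode positions come from the idealized 10-05 spherical
layout shipped with MNE-Python, projected to the unit sphere. All internal
times are seconds from recording start; sample indices are 0-based; epoch
windows are half-open `[start, end)` — one fixed convention removes every
±1-sample ambiguity downstream. Measures are stored long-format
(subject, group, occasion, run-or-"all", measure, value), the layout the
reliability estimators consume.

On-disk formats: BrainVision `.vhdr/.vmrk/.eeg` (multiplexed; IEEE float32
written, float32 and scaled int16 read) with a configurable marker code
map; run boundaries travel as standard Comment markers so a write→read
round trip reproduces the event table exactly (verified independently
against MNE's BrainVision reader). An internal archive format (binary
float64 matrix + JSON metadata + events TSV) round-trips losslessly. The
stimulus device's true marker codes are not public, so the defaults
(S1/S2 for standard/deviant tones, S11–13 visual, S21–23 auditory oddball,
S31 click train, R1 response) are package conventions.

## 2. Stimulus sequences

Generators reproduce the battery's printed design exactly for every seed:
3200 tones (90% standards at 633 Hz/50 ms, 10% pitch+duration deviants at
1000 Hz/100 ms) at a fixed 500 ms SOA over 5 runs, each run opening with 20
standards; 800 visual oddball stimuli (640/80/80) over the same 5 runs with
SOA uniform on a 1/60 s grid between 1.6 and 2.4 s; 800 auditory oddball
stimuli (640/80/80) over 4 runs, SOA uniform on a 25 ms grid between 1.1
and 1.4 s; 150 click trains (500 ms, clicks every 25 ms → 40 Hz drive) at a
1.5 s SOA; and 185 s of rest per eye condition. The fixed session schedule
(instructions, practices, and the alternating run order) sums to 57:23.

Choices the design leaves open, fixed here: "pseudo-random" order means a
constrained shuffle forbidding two consecutive rare stimuli; the 16.67 ms
visual jitter step is read as one 60 Hz display frame (1/60 s), with onsets
rounded to the 1 ms sample grid; visual onsets are resampled until every
one is ≥ 50 ms from every tone onset (the design requires non-simultaneity
without giving a number). Onsets are computed in integer milliseconds so
they are exactly representable at 1000 Hz and survive file round trips
bit-exactly.

## 3. Synthetic EEG

Each scored component is a kernel: a Gaussian time course (peak latency,
FWHM) with a smooth scalp topography (spatial Gaussian of chordal distance
to the peak electrode on the unit sphere, peak weight 1). Signals are
synthesized in the FCz-referenced frame — each channel receives
`topo(ch) − topo(FCz)` — so re-referencing behaves like real data.
Obligatory responses common to every stimulus of a modality are included;
they cancel exactly in the condition-difference waves used for scoring.

Component amplitudes are parameterized by the *scored* value (window mean ×
cluster mean under the common average reference), not the raw peak: the
realized target for person i at occasion j is `y_ij = μ + p_i + o_j + e_ij`
with `p_i ~ N(0, σ_p²)`, a fixed occasion shift `o_j`, and
`e_ij ~ N(0, σ²_po+e)`; the kernel is rescaled so the pipeline's score
equals `y_ij` up to filter tolerance. Habituation is multiplicative:
`× (1 − r_j)^(run−1) × s^(occasion−1)` with per-session decay rates `r_j`
(month-2 steeper by default) and a session scale `s` — two interpretable
parameters that reproduce declining run profiles and Session × Run
interactions.

The steady-state response is synthesized as an amplitude-modulated 40 Hz
sinusoid over the 500 ms train (not a click impulse train): the scored
quantities live in the 38–42 Hz band, and sinusoidal synthesis makes
ground-truth phase locking and power analytic. The trial phase is von Mises
with concentration κ (κ = ∞ → deterministic phase → ITC 1).

Noise model: 1/f background (default 10 µV RMS, exponent 1) mixed through a
smooth spatial kernel so neighboring electrodes correlate as on a real
scalp; amplitude-modulated posterior 10 Hz alpha with a 2× eyes-closed
gain; optional line noise; blinks (Poisson, ~300 ms bumps, frontal
topography peaking at Fp1/Fp2); muscle bursts (55–95 Hz, temporal electrode
groups); and optionally fully replaced "bad" channels. What the generator
does **not** emulate: a biophysical head-model forward solution, heartbeat
and sweat artifacts, non-stationary impedance drift, or the content of the
novel-sound corpus. Passing tests therefore demonstrate correctness of the
measurement and statistics chain, not robustness to every artifact class in
field data.

Behavior: hits on targets with configurable miss probability and log-normal
reaction times (per-person median driven by the same random-effects model),
sporadic false alarms on novels/standards.

A fast measure-level simulator (`simulate_measures`) skips the signal path
and draws balanced Person × Occasion tables directly from the
random-effects model; it is the workhorse for reliability recovery and
calibration tests. Default study conditions: measure means at realistic
magnitudes (e.g. −2 µV mismatch negativity, +5 µV P3b, ITC 0.30, 450 ms
median RT), person/residual SDs giving true G in the 0.6–0.85 range, small
negative session shifts for the habituating components, and run decay rates
of 5–8% (baseline) vs 8–11% (month 2).

## 4. Preprocessing

Fixed ERP chain: 0.2 Hz high-pass → 250 Hz downsample → bad-channel
detection/interpolation → robust common average reference → epoching
(mismatch negativity −0.5…0.5 s; oddballs −1…2 s; steady state
−1.248…1.756 s) → BSS-CCA muscle separation → ±3 SD epoch rejection →
ocular proxy regression → −100…0 ms baseline. Every stage is a pure
function of (input, config, seed); reruns are bit-identical.

Filters: zero-phase 4th-order Butterworth applied forward-backward, with
padding of 3/cutoff seconds because a sub-hertz high-pass has a
seconds-long impulse response; anti-alias 8th-order low-pass at 0.4× the
target rate before decimation. The acquisition chain names only cutoffs, so
filter families and orders are package choices.

Bad channels: robust z > 5 of robust amplitude (median absolute deviation),
maximum correlation with the 8 nearest spatial neighbors < 0.4 (a flat
channel has undefined correlation, treated as 0 and hence flagged), and
robust z > 5 of the high-frequency power fraction. Interpolation is a
spherical-spline estimate (Legendre expansion to order 50, stiffness 4,
ridge 1e-5).

Robust reference: iteratively estimate the mean over non-excluded, non-bad
channels, re-detect bads against that interim reference, repeat to
convergence (≤ 10 rounds, warning on failure); detected bads are
spline-interpolated and then rejoin the reference set; TP9/TP10/Fp1/Fp2
never contribute to the reference mean but do receive the final
subtraction; FCz is first reconstructed as an explicit zero channel so
FCz-containing clusters remain scorable.

Epoch rejection: the three per-epoch statistics (channel-mean amplitude,
channel-mean variance, channel-mean peak-to-peak) are z-scored across
epochs once — no re-iteration — and |z| ≥ 3 on any statistic rejects.
Statistics are computed on channel means (matching the published epoch
criteria of the FASTER method) rather than channel maxima; zero spread
defines z = 0, so degenerate identical epochs reject nothing.

Muscle separation: CCA between the concatenated epochs and their 1-sample
delay (lag covariances accumulated within epochs to avoid boundary
products), sources ordered by canonical correlation ≡ lag-1
autocorrelation. Sources with autocorrelation < 0.6 **and** > 50% of power
above 30 Hz are discarded; the mixing matrix is `C₀W` (the eigenvectors are
C₀-orthonormal), so reconstruction without removal is exact. Average
referencing costs exactly one dimension; that expected deficiency is
reduced silently.

Ocular cleaning replaces a trained component classifier with a
deterministic stage: the blink proxy is the Fp1/Fp2 mean band-passed
0.5–8 Hz across the concatenated epochs; samples beyond 5 robust SDs define
blink segments; per-channel regression slopes are fitted on those segments
only (intercept included) and the proxy contribution is subtracted
everywhere. On blink-free data essentially nothing is altered.

Resting chain: 0.5 Hz high-pass, 250 Hz downsample, common average,
bad-channel detection, the first 180 whole-second epochs (the run is
185 s; the design does not say which 180), rejection computed from clean
channels only, conservative ocular/muscle thresholds, interpolation of
bads, final common average.

## 5. Time-frequency analysis

Morlet kernels with σ_f = f/C and σ_t = 1/(2πσ_f), where C = 7 for
f ≤ 20 Hz, C = 14 for f ≥ 40 Hz, and linear in f between — which makes the
bandwidth 6σ_f exactly constant (120/7 ≈ 17.1429 Hz) on [20, 40]. Kernels
are truncated at ±3σ_t (duration 6σ_t) and amplitude-normalized (unit
sinusoid at the center frequency → |coefficient| ≈ 1); dB ratios and ITC
are invariant to this normalization constant. Frequencies run 4–100 Hz in
2 Hz bins; outputs are restricted to −248…752 ms, which the −1248…1752 ms
epochs guarantee is free of edge effects; no padding is used.

ITC is the mean resultant length of trial phases (1 − circular variance);
zero-magnitude coefficients have undefined phase and are excluded
pointwise. Total power is the trial-mean |c|², 10log10-transformed, then
baseline corrected by the −200…−100 ms mean per frequency (that order —
average, log, subtract — follows the published processing narrative).
Evoked power is |c|² of the trial-average waveform, baseline corrected in
*linear* units: the source pipeline states the dB transform for total power
only, and this implementation takes that literally rather than guessing
symmetry. Power below 1e-12 µV² is clipped before the log. For the
steady-state analysis the data are re-referenced to the mean of P7/P8
(near-mastoid) before decomposition, and measures are the mean over
100–500 ms, the 38/40/42 Hz bins, and the fronto-central clusters. The
production path is wavelet-only; an FFT-bandpass + Hilbert implementation
exists solely as an independent oracle inside the tests.

## 6. Resting spectra

The PSD method is unstated in the source pipeline; chosen here: per-epoch
Hamming-tapered periodograms averaged across the 1-s epochs (Welch with
non-overlapping 1 s segments), density-scaled so the integral over
frequency approximates the variance. "Absolute power" is the mean density
over a band's integer-frequency bins (delta 1–3, theta 4–7, alpha 8–12,
beta 13–30, gamma 31–48 Hz) averaged over the band's cluster; the
G-coefficient is invariant to the constant bandwidth factor that separates
mean density from the band integral.

## 7. Behavior

A press is attributed to the most recent stimulus whose response window
contains it, one press per stimulus. The window (100–1000 ms) is a package
default chosen below both tasks' minimum SOA so no press can be attributed
twice. The unit of analysis is the per-participant median RT over correct
targets.

## 8. Reliability statistics

For the balanced complete two-way layout (one observation per cell) the
variance components come from the ANOVA mean squares —
σ̂²_po+e = MS_res, σ̂²_p = (MS_P − MS_res)/n_o, σ̂²_o = (MS_O − MS_res)/n_p —
which coincide with REML at its optimum for this design; an iterative REML
path is deliberately out of scope (exactness and testability win at equal
answers). Incomplete persons are dropped (complete-case). Negative
estimates are truncated to zero before the G-coefficient, with the raw
values also reported, since the literature is silent on truncation.
G(n_o = 1) ≡ ICC(3,1) algebraically; the identity is verified to 1e-10 in
tests, with pingouin as an independent cross-check.

The Session × Run ANOVA uses orthonormal contrasts per subject: each
within-subject effect is tested against its own effect-by-subject error;
the Greenhouse-Geisser ε is the standard sample estimator
`tr(S)²/(q·tr(S²))` from the covariance of the contrast scores, clipped to
[1/q, 1]; Huynh-Feldt is not implemented. Polynomial trends are one-df
contrast F-tests for run-linear/quadratic and their session interactions.
The analysis pools groups (as the source analysis did for run effects);
group is available as a filter. No multiple-testing correction is applied
anywhere, matching the source analysis.

## 9. Problem sizes and tolerances in tests

Measure-level checks run at full statistical scale (n = 500 persons,
200–2000 replicates). EEG-level signal-path checks use shortened paradigm
runs (e.g. 120 tones, 60 oddball stimuli, 30 click trains) because with
noise and artifacts disabled the scored amplitude is deterministic and does
not depend on trial count; recovery is asserted within 2%, the measured
residual being filter shape and baseline interaction (≤ ~0.7% across
components). Controlled recovery experiments synthesize one component
family at a time (e.g. auditory kernels only when scoring the mismatch
negativity) so that cross-modal kernel overlap — which cancels only in
expectation — does not contaminate a zero-noise equality check; the
interleaved all-kernel condition is exercised separately with statistical
tolerances. The end-to-end EEG demonstration uses 4–8 persons; its
reliability table is a signal-path demonstration, not a precision estimate.

## 10. Known limitations

- The ocular stage removes blink-correlated variance only; lateral eye
  movements with antisymmetric frontal topography are not modeled by the
  proxy.
- The balanced-design estimator cannot exploit partially observed persons;
  with two fixed occasions this loses little, but unbalanced multi-occasion
  designs would need true REML.
- The synthetic alpha source is a single posterior oscillator; spatial
  alpha heterogeneity across persons is not modeled, so rest-measure
  reliability at EEG level is governed mostly by the noise seed rather than
  person traits (the measure-level simulator carries the person structure
  for those measures).
- BrainVision support covers the multiplexed float32/int16 dialects only
  (vectorized orientation and EDF/BDF are out of scope).
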