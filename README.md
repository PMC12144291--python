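# eegtrt — EEG biomarker measurement and test-retest reliability

`eegtrt` implements, end to end, the measurement and reliability pipeline of
a multi-site EEG biomarker battery for psychosis-risk research: five task
paradigms (an interleaved passive auditory oddball for the mismatch
negativity plus an active visual oddball, an active auditory oddball, a
40-Hz click-train steady-state paradigm, and eyes-open/eyes-closed rest),
their ERP / event-related-oscillation / spectral / behavioral measures, and
a generalizability-theory analysis of how reproducible those measures are
between a baseline and a two-month follow-up session.

Because the corresponding human recordings are controlled-access, the
package is built around a first-class synthetic-data module: it generates
paradigm-exact stimulus sequences and full 63-channel, 1000 Hz recordings
with known ground truth (component amplitudes, phase-locking concentration,
person/occasion/error variance structure, habituation rates, artifacts), so
every stage of the pipeline is testable against analytically known answers.

## What it computes

**Measures.** Mismatch negativity (deviant−standard difference wave,
86–166 ms, fronto-central cluster), auditory/visual target P3b and novel
P3a (±40 ms windows on their grand-average peaks, centro-parietal or
fronto-central clusters), 40-Hz auditory steady-state inter-trial coherence
and evoked/total power (Morlet wavelets with σ_f = f/C, C = 7→14;
38–42 Hz × 100–500 ms), resting band power (delta…gamma, Welch PSD on 180
one-second epochs), and oddball performance (miss/false-alarm rates, median
reaction time).

**Preprocessing.** 0.2 Hz zero-phase high-pass, downsampling to 250 Hz,
PREP-style bad-channel detection and spherical-spline interpolation, a
robust common average reference that excludes the mastoids (TP9/TP10) and
Fp1/Fp2 from the reference mean, epoching, BSS-CCA muscle-artifact
separation, ±3 SD outlier-epoch rejection (mean amplitude / variance /
peak-to-peak), an Fp1/Fp2 blink-proxy regression, and −100…0 ms baseline
correction.

**Reliability.** For a fully crossed Persons × Occasion design with
variance components σ²_p, σ²_o, σ²_po+e, the G-coefficient

    G = σ²_p / (σ²_p + σ²_po+e / n_o)

with n_o = 1 (equal to ICC(3,1)), categorized as poor (< 0.4), fair
(0.4–0.6), good (0.6–0.75), or excellent (0.75–1.0). Mean stability is
tested with paired t-tests; changes across task runs with a Session × Run
repeated-measures ANOVA, Greenhouse-Geisser adjusted, with orthonormal
linear/quadratic trend contrasts.

## Worked example

Simulate a measure-level study and estimate reliability:

```sh
python analysis/01_simulate_study.py
python analysis/02_reliability_report.py
```

which prints, for the 571-person simulated high-risk cohort (truncated):

```
        measure      G  category       t      p
            mmn 0.7424      good  6.8318 0.0000
        aod_p3b 0.7424      good -7.9059 0.0000
        aod_p3a 0.7267      good -3.6261 0.0003
        vod_p3b 0.7900 excellent -6.2222 0.0000
       assr_itc 0.6900      good -1.7578 0.0793
  aod_median_rt 0.7769 excellent -2.2656 0.0239
mean G = 0.74  (range 0.49-0.87)
```

`G` is the test-retest generalizability coefficient of each measure over
the two sessions; `t`/`p` test the session-2 minus session-1 mean change
(the significant negative t values for the P300s reflect the simulated
habituation across sessions; the positive t for the mismatch negativity is
the same magnitude decline, since that component is negative-going).

`analysis/03_habituation_anova.py` runs the Session × Run ANOVA on per-run
scores, and `analysis/04_eeg_signal_path.py` demonstrates the full
EEG-level chain (synthesize → preprocess → score → reliability) on a small
cohort. The same steps are available as a CLI
(`eegtrt simulate|preprocess|score|reliability|run`).

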