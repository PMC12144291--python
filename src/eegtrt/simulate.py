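"""Synthetic EEG sessions and measure-level study simulation with known truth.

Two levels of simulation are provided:

* :func:`synthesize_session` renders a full 63-channel, 1000 Hz recording for
  a stimulus sequence: each event adds a component kernel (a Gaussian bump in
  time with a smooth scalp topography) scaled by person/occasion/habituation
  factors; click trains add a 40-Hz amplitude-modulated sinusoid whose trial
  phase is von Mises distributed with concentration kappa; on top sit 1/f
  background noise, posterior alpha (boosted eyes-closed), optional line
  noise, blinks (frontal), muscle bursts (temporal, high-frequency), and
  optional bad channels.
* :func:`simulate_measures` skips the signal path and draws analysis-ready
  measure tables directly from the persons x occasions random-effects model
  ``y_ij = mu + p_i + o_j + e_ij``, which is the model the reliability
  analyses estimate.

Component amplitudes are parameterized by the *scored* value (window mean x
cluster mean), so the ground truth written next to a synthetic session is in
the same units the scoring pipeline reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    EVENT_COLUMNS,
    MEASURE_COLUMNS,
    EventTable,
    Montage,
    RawSession,
    SessionMeta,
    standard_montage,
)

__all__ = [
    "ComponentKernel",
    "MeasureTruth",
    "NoiseSpec",
    "BehaviorSpec",
    "StudyTruth",
    "default_kernels",
    "default_study_truth",
    "gaussian_topography",
    "synthesize_session",
    "simulate_measures",
    "simulate_run_measures",
    "draw_person_effects",
]

OCCASIONS = ("baseline", "month2")


def _window_grid_ms(window_ms, dt_ms: float = 4.0) -> np.ndarray:
    """Sample times (ms) of the 250 Hz epoch grid falling in the closed window."""
    lo, hi = window_ms
    first = math.ceil(lo / dt_ms - 1e-9) * dt_ms
    return np.arange(first, hi + 1e-9, dt_ms)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentKernel:
    """A stereotyped evoked response: Gaussian time course + scalp topography.

    ``peak_amplitude_uv`` is the signed peak of the time course at the peak
    electrode (topography weight 1). ``kind='oscillation'`` kernels instead
    add a windowed sinusoid at ``osc_freq_hz`` (used for the steady-state
    response).
    """

    name: str
    peak_latency_ms: float
    half_width_ms: float  # FWHM of the Gaussian time course
    peak_amplitude_uv: float
    peak_electrode: str
    topography: dict[str, float]
    kind: str = "transient"  # or "oscillation"
    osc_freq_hz: float = 40.0
    osc_duration_ms: float = 500.0

    def __post_init__(self):
        if any(abs(w) > 1 + 1e-9 for w in self.topography.values()):
            raise ValueError("topography weights must lie in [-1, 1]")

    @property
    def sigma_s(self) -> float:
        return self.half_width_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak time course evaluated at times ``t`` (s, event-relative)."""
        if self.kind == "oscillation":
            dur = self.osc_duration_ms / 1000.0
            env = np.where((t >= 0) & (t < dur),
                           np.sin(np.pi * np.clip(t, 0, dur) / dur) ** 0.5, 0.0)
            return env * np.sin(2 * np.pi * self.osc_freq_hz * t)
        lat = self.peak_latency_ms / 1000.0
        return np.exp(-0.5 * ((t - lat) / self.sigma_s) ** 2)

    def expected_score(self, window_ms: tuple[float, float],
                       cluster: tuple[str, ...], dt_ms: float = 4.0) -> float:
        """Scored value of the pure kernel: time mean over the window samples
        then mean of topography weights over the cluster, times the peak.

        Samples sit on the epoch grid (multiples of ``dt_ms`` from onset),
        matching the 250 Hz scoring path.
        """
        t = _window_grid_ms(window_ms, dt_ms) / 1000.0
        wmean = float(np.mean(self.waveform(t)))
        topo = float(np.mean([self.topography[c] for c in cluster]))
        return self.peak_amplitude_uv * wmean * topo


def gaussian_topography(montage: Montage, peak_electrode: str,
                        spatial_sigma: float = 0.6) -> dict[str, float]:
    """Smooth scalp field: weight = exp(-d^2 / 2 sigma^2) of the chordal
    distance to the peak electrode on the unit sphere; peak weight 1."""
    labels = list(montage.channel_labels)
    if montage.reference_label not in labels:
        labels.append(montage.reference_label)
    p0 = montage.positions[peak_electrode]
    out = {}
    for lb in labels:
        d = float(np.linalg.norm(montage.positions[lb] - p0))
        out[lb] = math.exp(-0.5 * (d / spatial_sigma) ** 2)
    return out


#: (paradigm, modality, condition) whose events carry each scored component.
KERNEL_EVENTS: dict[str, tuple[str, str, tuple[str, ...]]] = {
    "mmn": ("mmn_vod", "auditory", ("deviant",)),
    "aod_p3b": ("aod", "auditory", ("target",)),
    "aod_p3a": ("aod", "auditory", ("novel",)),
    "vod_p3b": ("mmn_vod", "visual", ("target",)),
    "vod_p3a": ("mmn_vod", "visual", ("novel",)),
    "assr": ("assr", "click_train", ("train",)),
    # obligatory responses common to all stimuli of a modality; these cancel
    # exactly in the difference waves used for scoring
    "aud_obligatory": ("mmn_vod", "auditory", ("standard", "deviant")),
    "aod_obligatory": ("aod", "auditory", ("standard", "target", "novel")),
    "vis_obligatory": ("mmn_vod", "visual", ("standard", "target", "novel")),
}


def default_kernels(montage: Montage | None = None) -> dict[str, ComponentKernel]:
    """Kernels emulating the scored components, at their observed latencies."""
    montage = montage or standard_montage()

    def topo(peak):
        return gaussian_topography(montage, peak)

    return {
        "mmn": ComponentKernel("mmn", 126.0, 60.0, -1.0, "FCz", topo("FCz")),
        "aod_p3b": ComponentKernel("aod_p3b", 339.0, 120.0, 1.0, "Pz", topo("Pz")),
        "aod_p3a": ComponentKernel("aod_p3a", 316.0, 110.0, 1.0, "Cz", topo("Cz")),
        "vod_p3b": ComponentKernel("vod_p3b", 433.0, 130.0, 1.0, "Pz", topo("Pz")),
        "vod_p3a": ComponentKernel("vod_p3a", 372.0, 120.0, 1.0, "CPz", topo("CPz")),
        "assr": ComponentKernel("assr", 0.0, 0.0, 1.0, "FCz", topo("FCz"),
                                kind="oscillation"),
        "aud_obligatory": ComponentKernel("aud_obligatory", 100.0, 50.0, -0.8,
                                          "Cz", topo("Cz")),
        "aod_obligatory": ComponentKernel("aod_obligatory", 100.0, 50.0, -0.8,
                                          "Cz", topo("Cz")),
        "vis_obligatory": ComponentKernel("vis_obligatory", 120.0, 60.0, 1.0,
                                          "Oz", topo("Oz")),
    }


# ---------------------------------------------------------------------------
# Study truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureTruth:
    """Random-effects truth for one measure: y_ij = mu + p_i + o_j + e_ij."""

    mu: float
    person_sd: float
    occasion_shift: float = 0.0  # fixed shift added at month-2
    residual_sd: float = 0.0  # persons x occasion interaction + error

    def __post_init__(self):
        if not (self.person_sd >= 0 and self.residual_sd >= 0):
            raise ValueError("SDs must be non-negative and finite")

    @property
    def g_true(self) -> float:
        denom = self.person_sd ** 2 + self.residual_sd ** 2
        return 0.0 if denom == 0 else self.person_sd ** 2 / denom


@dataclass(frozen=True)
class NoiseSpec:
    background_rms_uv: float = 10.0
    one_over_f_exponent: float = 1.0
    spatial_smoothness: float = 0.4  # mixing width on the unit sphere; 0 = independent
    alpha_freq_hz: float = 10.0
    alpha_rms_uv: float = 4.0
    alpha_closed_gain: float = 2.0
    line_freq_hz: float = 60.0
    line_amp_uv: float = 0.0
    blink_rate_hz: float = 0.10
    blink_amp_uv: float = 80.0
    muscle_rate_hz: float = 0.05
    muscle_amp_uv: float = 20.0
    bad_channels: tuple[str, ...] = ()

    def silent(self) -> "NoiseSpec":
        """All artifact and noise sources disabled (signal-path testing)."""
        return replace(self, background_rms_uv=0.0, alpha_rms_uv=0.0,
                       line_amp_uv=0.0, blink_rate_hz=0.0, muscle_rate_hz=0.0,
                       bad_channels=())


@dataclass(frozen=True)
class BehaviorSpec:
    miss_prob: float = 0.05
    fa_novel_prob: float = 0.02
    fa_standard_prob: float = 0.005
    rt_median_s: float = 0.45
    rt_log_sd: float = 0.25
    response_delay_jitter_s: float = 0.0


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameters of a simulated test-retest study."""

    measures: dict[str, MeasureTruth]
    run_decay: dict[str, tuple[float, float]] = field(default_factory=dict)
    session_scale: dict[str, float] = field(default_factory=dict)
    noise: NoiseSpec = NoiseSpec()
    behavior: BehaviorSpec = BehaviorSpec()
    assr_phase_jitter_kappa: float = 1.0  # inf = perfect phase locking

    def habituation_factor(self, name: str, run_index: int, occasion: str) -> float:
        r = self.run_decay.get(name, (0.0, 0.0))
        j = OCCASIONS.index(occasion)
        s = self.session_scale.get(name, 1.0)
        if not (0.0 <= r[j] <= 1.0):
            raise ValueError("run decay rates must lie in [0, 1]")
        return (1.0 - r[j]) ** (run_index - 1) * s ** j


def default_study_truth() -> StudyTruth:
    """Study conditions used throughout: measure means at realistic magnitudes,
    person/residual SDs giving good-to-excellent reliability, small session
    declines, and mild per-run habituation."""
    m = {
        "mmn": MeasureTruth(-2.0, 0.70, +0.15, 0.40),
        "aod_p3b": MeasureTruth(5.0, 1.60, -0.40, 0.95),
        "aod_p3a": MeasureTruth(3.5, 1.30, -0.25, 0.85),
        "vod_p3b": MeasureTruth(5.0, 1.70, -0.35, 0.95),
        "vod_p3a": MeasureTruth(3.5, 1.40, -0.30, 0.90),
        "assr_itc": MeasureTruth(0.30, 0.080, -0.01, 0.055),
        "assr_evoked": MeasureTruth(0.60, 0.20, -0.03, 0.13),
        "assr_total": MeasureTruth(1.20, 0.40, -0.06, 0.28),
        "aod_median_rt": MeasureTruth(450.0, 80.0, -5.0, 42.0),
        "vod_median_rt": MeasureTruth(500.0, 85.0, -5.0, 45.0),
    }
    for cond in ("open", "closed"):
        for band, (mu, sp, se) in {
            "delta": (8.0, 3.0, 1.5), "theta": (6.0, 2.5, 1.1),
            "alpha": (10.0, 5.0, 1.9), "beta": (3.0, 1.2, 0.75),
            "gamma": (1.0, 0.40, 0.40),
        }.items():
            m[f"rest_{cond}_{band}"] = MeasureTruth(mu, sp, 0.0, se)
    run_decay = {
        "mmn": (0.05, 0.08), "aod_p3b": (0.06, 0.09), "aod_p3a": (0.08, 0.11),
        "vod_p3b": (0.06, 0.09), "vod_p3a": (0.08, 0.11),
    }
    session_scale = {k: 0.95 for k in ("mmn", "aod_p3b", "aod_p3a",
                                       "vod_p3b", "vod_p3a", "assr")}
    return StudyTruth(measures=m, run_decay=run_decay, session_scale=session_scale)


def draw_person_effects(truth: StudyTruth, n_persons: int, seed: int
                        ) -> pd.DataFrame:
    """Draw p_i ~ N(0, person_sd^2) for every measure; persons x measures."""
    rng = np.random.default_rng(seed)
    cols = {name: rng.normal(0.0, mt.person_sd, size=n_persons)
            for name, mt in truth.measures.items()}
    return pd.DataFrame(cols, index=[f"S{i:04d}" for i in range(1, n_persons + 1)])


# ---------------------------------------------------------------------------
# EEG-level synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng, n_ch, n_samp, fs, rms, exponent):
    white = rng.standard_normal((n_ch, n_samp))
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = (np.maximum(freqs[nz], 0.5)) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = np.fft.rfft(white, axis=1) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def synthesize_session(
    events: EventTable,
    kernels: dict[str, ComponentKernel],
    truth: StudyTruth,
    person_effects: dict[str, float],
    occasion: str = "baseline",
    seed: int = 0,
    *,
    paradigm: str | None = None,
    duration_s: float | None = None,
    montage: Montage | None = None,
    sampling_rate: float = 1000.0,
    meta: SessionMeta | None = None,
) -> tuple[RawSession, dict[str, float]]:
    """Render one paradigm segment as a continuous 63-channel recording.

    Returns the session together with the realized per-measure target values
    (mu + p_i + o_j + e_ij before habituation) for test assertions. For rest
    segments pass an empty event table plus ``paradigm`` and ``duration_s``.
    """
    rng = np.random.default_rng(seed)
    montage = montage or standard_montage()
    fs = float(sampling_rate)
    j = OCCASIONS.index(occasion)

    if paradigm is None:
        if len(events) == 0:
            raise ValueError("paradigm required for event-free segments")
        paradigm = events.df["paradigm"].iloc[0]
    if duration_s is None:
        duration_s = float(events.onsets.max()) + 3.0 if len(events) else 185.0
    n_samp = int(round(duration_s * fs))
    data = np.zeros((montage.n_channels, n_samp))
    ch_index = {lb: i for i, lb in enumerate(montage.channel_labels)}

    # realized measure targets for this person x occasion
    realized: dict[str, float] = {}
    for name, mt in truth.measures.items():
        p = person_effects.get(name, 0.0)
        e = rng.normal(0.0, mt.residual_sd) if mt.residual_sd > 0 else 0.0
        realized[name] = mt.mu + p + j * mt.occasion_shift + e

    def topo_vector(kernel, referenced: bool = True):
        """Topography in the recorded (FCz-referenced) frame: the online
        reference's own field is subtracted from every channel."""
        v = np.zeros(montage.n_channels)
        for lb, w in kernel.topography.items():
            if lb in ch_index:
                v[ch_index[lb]] = w
        if referenced:
            v = v - kernel.topography.get(montage.reference_label, 0.0)
        return v

    # channels contributing to the common average reference used for scoring
    car_labels = [lb for lb in (*montage.channel_labels, montage.reference_label)
                  if lb not in ("TP9", "TP10", "Fp1", "Fp2")]

    def unit_score_car(kernel, cdef) -> float:
        """Scored value of a unit-amplitude kernel after average referencing:
        window mean x (cluster topography mean - reference-set mean)."""
        t = _window_grid_ms(cdef.score_window_ms) / 1000.0
        wmean = float(np.mean(np.exp(
            -0.5 * ((t - kernel.peak_latency_ms / 1000.0) / kernel.sigma_s) ** 2)))
        topo_cl = float(np.mean([kernel.topography[c] for c in cdef.cluster]))
        topo_car = float(np.mean([kernel.topography.get(lb, 0.0)
                                  for lb in car_labels]))
        return wmean * (topo_cl - topo_car)

    kappa = truth.assr_phase_jitter_kappa

    for name, kernel in kernels.items():
        if name not in KERNEL_EVENTS:
            continue
        ev_paradigm, modality, conditions = KERNEL_EVENTS[name]
        if ev_paradigm != paradigm:
            continue
        sel = events.select(modality=modality, condition=conditions)
        if len(sel) == 0:
            continue
        missing = [lb for lb in kernel.topography
                   if lb not in ch_index and lb != montage.reference_label]
        if missing:
            raise ValueError(f"kernel {name} names unknown electrodes {missing}")
        topo = topo_vector(kernel)

        if kernel.kind == "oscillation":
            # effective cluster amplitude under the P7/P8 scoring reference
            ev_cluster = ("Fz", "F1", "F2", "FCz", "FC1", "FC2")
            topo_cl = float(np.mean([kernel.topography[c] for c in ev_cluster]))
            topo_ref = 0.5 * (kernel.topography.get("P7", 0.0)
                              + kernel.topography.get("P8", 0.0))
            eff = max(topo_cl - topo_ref, 1e-6)
            amp_meas = realized.get("assr_evoked", kernel.peak_amplitude_uv) / eff
            amp = amp_meas * truth.session_scale.get("assr", 1.0) ** j
            dur = kernel.osc_duration_ms / 1000.0
            n_k = int(round(dur * fs))
            t_rel = np.arange(n_k) / fs
            for onset in sel.onsets:
                theta = 0.0 if not np.isfinite(kappa) else float(
                    rng.vonmises(0.0, max(kappa, 1e-12)))
                env = np.sin(np.pi * t_rel / dur) ** 0.5
                wave = amp * env * np.sin(2 * np.pi * kernel.osc_freq_hz * t_rel
                                          + theta)
                i0 = int(round(onset * fs))
                data[:, i0:i0 + n_k] += topo[:, None] * wave[None, :]
            continue

        # transient kernel: scale so the *scored* value (cluster/window mean
        # of the difference wave under the average reference) equals the
        # realized measure target; obligatory kernels keep nominal amplitude
        from .erp import DEFAULT_COMPONENTS  # local import avoids cycle at import time
        if name in DEFAULT_COMPONENTS and name in realized:
            base = unit_score_car(kernel, DEFAULT_COMPONENTS[name])
            scale = realized[name] / base if base != 0 else 0.0
        else:
            scale = kernel.peak_amplitude_uv
        half = 4.0 * kernel.sigma_s
        lat = kernel.peak_latency_ms / 1000.0
        n_k = int(round(2 * half * fs)) + 1
        t_rel = lat - half + np.arange(n_k) / fs
        wave_unit = kernel.waveform(t_rel)
        for onset, run in zip(sel.onsets, sel.df["run_index"].to_numpy()):
            hab = truth.habituation_factor(name, int(run), occasion)
            i0 = int(round((onset + lat - half) * fs))
            a, b = max(i0, 0), min(i0 + n_k, n_samp)
            if b <= a:
                continue
            data[:, a:b] += (scale * hab) * topo[:, None] * wave_unit[None, a - i0:b - i0]

    # ------------------------------------------------------------------ noise
    ns = truth.noise
    if ns.background_rms_uv > 0:
        bg = _one_over_f_noise(rng, montage.n_channels, n_samp, fs,
                               ns.background_rms_uv, ns.one_over_f_exponent)
        if ns.spatial_smoothness > 0:
            # smooth source mixing so neighboring electrodes correlate, as on
            # a real scalp; rows unit-norm to preserve the per-channel RMS
            pos = montage.position_array(montage.channel_labels)
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
            M = np.exp(-0.5 * (d / ns.spatial_smoothness) ** 2)
            M /= np.linalg.norm(M, axis=1, keepdims=True)
            bg = M @ bg
        data += bg
    if ns.alpha_rms_uv > 0:
        gain = ns.alpha_closed_gain if paradigm == "rest_closed" else 1.0
        t = np.arange(n_samp) / fs
        # slowly amplitude-modulated posterior alpha
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        osc = np.sin(2 * np.pi * ns.alpha_freq_hz * t + rng.uniform(0, 2 * np.pi))
        topo = topo_vector(ComponentKernel("alpha", 0, 1, 1.0, "POz",
                                           gaussian_topography(montage, "POz", 0.5)))
        data += (gain * ns.alpha_rms_uv * math.sqrt(2.0)) * topo[:, None] * (env * osc)[None, :]
    if ns.line_amp_uv > 0:
        t = np.arange(n_samp) / fs
        data += ns.line_amp_uv * np.sin(2 * np.pi * ns.line_freq_hz * t)[None, :]
    if ns.blink_rate_hz > 0 and ns.blink_amp_uv > 0:
        n_blinks = rng.poisson(ns.blink_rate_hz * duration_s)
        fp_mid = 0.5 * (montage.positions["Fp1"] + montage.positions["Fp2"])
        topo = np.array([math.exp(-0.5 * (np.linalg.norm(
            montage.positions[lb] - fp_mid) / 0.35) ** 2)
            for lb in montage.channel_labels])
        n_b = int(0.3 * fs)
        bw = np.sin(np.pi * np.arange(n_b) / n_b) ** 2  # 300 ms bump
        for t0 in rng.uniform(0, duration_s - 0.4, size=n_blinks):
            i0 = int(t0 * fs)
            amp = ns.blink_amp_uv * rng.uniform(0.7, 1.3)
            data[:, i0:i0 + n_b] += amp * topo[:, None] * bw[None, :]
    if ns.muscle_rate_hz > 0 and ns.muscle_amp_uv > 0:
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [55.0, 95.0], btype="bandpass", fs=fs, output="sos")
        for side in (("T7", "FT7", "TP7"), ("T8", "FT8", "TP8")):
            n_bursts = rng.poisson(0.5 * ns.muscle_rate_hz * duration_s)
            idx = [ch_index[lb] for lb in side if lb in ch_index]
            for t0 in rng.uniform(0, duration_s - 0.6, size=n_bursts):
                i0 = int(t0 * fs)
                n_b = int(0.5 * fs)
                burst = sosfiltfilt(sos, rng.standard_normal(n_b + 200))[100:-100]
                burst *= ns.muscle_amp_uv / max(burst.std(), 1e-12)
                burst *= np.sin(np.pi * np.arange(n_b) / n_b)
                for k, i_ch in enumerate(idx):
                    data[i_ch, i0:i0 + n_b] += burst * (1.0 - 0.25 * k)
    for lb in ns.bad_channels:
        data[ch_index[lb]] = 100.0 * ns.background_rms_uv * rng.standard_normal(n_samp) \
            if ns.background_rms_uv > 0 else 1000.0 * rng.standard_normal(n_samp)

    # ------------------------------------------------------- behavior events
    all_events = events
    if paradigm in ("mmn_vod", "aod") and len(events):
        all_events = _with_responses(events, truth, person_effects, rng, paradigm,
                                     occasion=occasion)

    meta = meta or SessionMeta(subject_id="synthetic")
    session = RawSession(data=data, sampling_rate=fs, montage=montage,
                         events=all_events, meta=meta)
    return session, realized


def _with_responses(events, truth, person_effects, rng, paradigm, occasion):
    """Emit button responses: hits on targets (1 - miss_prob) with log-normal
    RT, sporadic false alarms on novels/standards."""
    bh = truth.behavior
    rt_name = f"{paradigm.split('_')[0]}_median_rt".replace("mmn", "vod")
    j = OCCASIONS.index(occasion)
    mt = truth.measures.get(rt_name)
    if mt is not None:
        med_ms = mt.mu + person_effects.get(rt_name, 0.0) + j * mt.occasion_shift \
            + (rng.normal(0.0, mt.residual_sd) if mt.residual_sd > 0 else 0.0)
    else:
        med_ms = bh.rt_median_s * 1000.0
    med_ms = max(med_ms, 150.0)

    rows = []
    stim = events.df[events.df["modality"] != "response"]
    vis_or_aud = "visual" if paradigm == "mmn_vod" else "auditory"
    for row in stim.itertuples():
        if paradigm == "mmn_vod" and row.modality != vis_or_aud:
            continue
        if row.condition == "target":
            p_resp = 1.0 - bh.miss_prob
        elif row.condition == "novel":
            p_resp = bh.fa_novel_prob
        elif row.condition == "standard":
            p_resp = bh.fa_standard_prob
        else:
            continue
        if rng.uniform() >= p_resp:
            continue
        rt_s = math.exp(math.log(med_ms / 1000.0) + rng.normal(0.0, bh.rt_log_sd))
        rt_s = float(np.clip(rt_s, 0.15, 0.95))
        rows.append(dict(onset=round(row.onset + rt_s, 3), code="R1",
                         modality="response", condition="button",
                         run_index=row.run_index, paradigm=row.paradigm))
    if not rows:
        return events
    resp = pd.DataFrame.from_records(rows, columns=EVENT_COLUMNS)
    df = pd.concat([events.df, resp], ignore_index=True)
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    # break exact onset ties (response landing on a stimulus sample)
    on = df["onset"].to_numpy(float).copy()
    for i in range(1, len(on)):
        if on[i] <= on[i - 1]:
            on[i] = on[i - 1] + 1e-3
    df["onset"] = on
    return EventTable(df, validate=False)


# ---------------------------------------------------------------------------
# Measure-level simulation
# ---------------------------------------------------------------------------

def simulate_measures(truth: StudyTruth, n_persons: int, n_occasions: int = 2,
                      seed: int = 0, group: str = "CON") -> pd.DataFrame:
    """Draw a balanced complete measure table from y_ij = mu + p_i + o_j + e_ij.

    Occasion effects are the fixed shifts in ``truth`` applied at the second
    and later occasions (scaled linearly with occasion index).
    """
    if n_persons < 2 or n_occasions < 2:
        raise ValueError("need at least 2 persons and 2 occasions")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:04d}" for i in range(1, n_persons + 1)]
    occ_names = ["baseline", "month2"] + [f"occ{j}" for j in range(3, n_occasions + 1)]
    frames = []
    for name, mt in truth.measures.items():
        if not np.isfinite(mt.person_sd) or not np.isfinite(mt.residual_sd):
            raise ValueError("non-finite variance")
        p = rng.normal(0.0, mt.person_sd, size=n_persons)
        e = rng.normal(0.0, mt.residual_sd, size=(n_persons, n_occasions))
        y = mt.mu + p[:, None] + mt.occasion_shift * np.arange(n_occasions)[None, :] + e
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(subjects, n_occasions),
            "group": group,
            "occasion": np.tile(occ_names[:n_occasions], n_persons),
            "run_index": "all",
            "measure_name": name,
            "value": y.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)[MEASURE_COLUMNS]


def simulate_run_measures(truth: StudyTruth, measure: str, n_persons: int,
                          n_runs: int, seed: int = 0,
                          run_noise_sd: float | None = None) -> np.ndarray:
    """Per-run scores for two sessions: array (persons, 2 sessions, n_runs).

    y_ijr = (mu + p_i + o_j + e_ijr) * (1 - r_j)^(run-1) * s^(j-1), with the
    per-session decay rates r_j and session scale s taken from ``truth``.
    """
    mt = truth.measures[measure]
    rng = np.random.default_rng(seed)
    sd_r = mt.residual_sd if run_noise_sd is None else run_noise_sd
    p = rng.normal(0.0, mt.person_sd, size=n_persons)
    out = np.empty((n_persons, 2, n_runs))
    for j, occ in enumerate(OCCASIONS):
        base = mt.mu + p + j * mt.occasion_shift
        for r_idx in range(n_runs):
            hab = truth.habituation_factor(measure, r_idx + 1, occ)
            e = rng.normal(0.0, sd_r, size=n_persons)
            out[:, j, r_idx] = (base + e) * hab
    return out
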