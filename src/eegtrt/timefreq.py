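"""Morlet wavelet time-frequency analysis for the 40-Hz steady-state response.

Each center frequency f gets a complex Morlet kernel with spectral width
sigma_f = f / C, where the constant C trades temporal against spectral
resolution: C = 7 at and below 20 Hz, C = 14 at and above 40 Hz, linear in f
in between - a schedule that keeps the bandwidth 6 sigma_f constant
(17.1429 Hz) across the 20-40 Hz transition band. Kernels are truncated at
+/- 3 sigma_t (duration 6 sigma_t) and amplitude-normalized so the
coefficient magnitude of a unit sinusoid at the center frequency is ~1.

From the coefficients: inter-trial coherence (ITC) is the mean resultant
length of trial phases (1 minus the circular phase-angle variance); total
power is the trial-mean squared magnitude, 10log10-transformed, baseline
corrected against -200..-100 ms; evoked power is the squared magnitude of
the trial-average waveform's coefficients, baseline corrected in linear
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import MEASURE_COLUMNS
from .preprocess import EpochSet

__all__ = [
    "WaveletSpec",
    "TFResult",
    "wavelet_spec",
    "morlet_kernel",
    "morlet_transform",
    "itc",
    "total_power",
    "evoked_power",
    "assr_time_frequency",
    "extract_assr_measures",
    "ASSR_FREQS",
    "ASSR_CLUSTERS",
]

ASSR_FREQS = np.arange(4.0, 100.0 + 1e-9, 2.0)  # 2-Hz bins, 4-100 Hz
ASSR_OUTPUT_WINDOW_MS = (-248.0, 752.0)
ASSR_BASELINE_MS = (-200.0, -100.0)
ASSR_MEASURE_BINS = (38.0, 40.0, 42.0)
ASSR_MEASURE_WINDOW_MS = (100.0, 500.0)
POWER_FLOOR = 1e-12  # microvolts^2, guard before log

ASSR_CLUSTERS = {
    "assr_itc": ("FCz", "FC1", "FC2", "Cz", "C1", "C2"),
    "assr_total": ("FCz", "FC1", "FC2", "Cz", "C1", "C2"),
    "assr_evoked": ("Fz", "F1", "F2", "FCz", "FC1", "FC2"),
}


@dataclass(frozen=True)
class WaveletSpec:
    center_frequency: float
    constant: float
    sigma_f: float
    sigma_t: float
    duration: float  # 6 sigma_t, seconds


def wavelet_spec(f: float) -> WaveletSpec:
    """Frequency-dependent Morlet parameters: C = 7 (f <= 20), 14 (f >= 40),
    linear between."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f <= 20.0:
        C = 7.0
    elif f >= 40.0:
        C = 14.0
    else:
        C = 7.0 + 7.0 * (f - 20.0) / 20.0
    sigma_f = f / C
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    return WaveletSpec(f, C, sigma_f, sigma_t, 6.0 * sigma_t)


def morlet_kernel(f: float, fs: float) -> np.ndarray:
    """Complex Morlet kernel truncated at +/- 3 sigma_t, amplitude-normalized."""
    spec = wavelet_spec(f)
    half = int(np.ceil(3.0 * spec.sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-0.5 * (t / spec.sigma_t) ** 2)
    kern = env * np.exp(2j * np.pi * f * t)
    # unit sinusoid at f -> |coefficient| ~ 1
    return kern * (2.0 / env.sum())


@dataclass
class TFResult:
    kind: str  # itc | total_power_db | evoked_power
    values: np.ndarray  # channels x frequencies x time
    frequency_axis: np.ndarray
    time_axis: np.ndarray  # seconds
    channel_labels: tuple[str, ...]
    n_trials: int
    n_excluded_points: int = 0

    def at(self, channel: str, freq: float) -> np.ndarray:
        ic = self.channel_labels.index(channel)
        i_f = int(np.argmin(np.abs(self.frequency_axis - freq)))
        return self.values[ic, i_f]

    def save(self, path) -> None:
        """Binary value array plus a JSON metadata sidecar."""
        import json
        from pathlib import Path
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        path.with_suffix(".json").write_text(json.dumps({
            "kind": self.kind,
            "frequency_axis": self.frequency_axis.tolist(),
            "time_axis": self.time_axis.tolist(),
            "channel_labels": list(self.channel_labels),
            "n_trials": self.n_trials,
            "n_excluded_points": self.n_excluded_points}))

    @classmethod
    def load(cls, path) -> "TFResult":
        import json
        from pathlib import Path
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(kind=meta["kind"], values=np.load(path.with_suffix(".npy")),
                   frequency_axis=np.asarray(meta["frequency_axis"]),
                   time_axis=np.asarray(meta["time_axis"]),
                   channel_labels=tuple(meta["channel_labels"]),
                   n_trials=meta["n_trials"],
                   n_excluded_points=meta["n_excluded_points"])


def _output_slice(times: np.ndarray, fs: float, freqs,
                  tmin: float, tmax: float) -> np.ndarray:
    max_half = max(int(np.ceil(3.0 * wavelet_spec(f).sigma_t * fs)) for f in freqs)
    mask = (times >= tmin - 1e-9) & (times <= tmax + 1e-9)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError("output window outside epoch")
    if idx[0] < max_half or idx[-1] > len(times) - 1 - max_half:
        raise ValueError("epoch too short for the requested wavelets and window")
    return idx


def morlet_transform(data: np.ndarray, times: np.ndarray, fs: float,
                     freqs=ASSR_FREQS,
                     output_window_s: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Convolve epochs (trials x channels x time) with Morlet kernels.

    Returns (coefficients, out_times); coefficients have shape
    (trials, channels, n_freqs, n_out_times), restricted to the valid output
    window (edges where the kernel would run off the epoch raise).
    """
    data = np.asarray(data)
    single = data.ndim == 2
    if single:
        data = data[None]
    freqs = np.atleast_1d(np.asarray(freqs, float))
    if output_window_s is None:
        tmin, tmax = times[0], times[-1]
        max_half = max(int(np.ceil(3.0 * wavelet_spec(f).sigma_t * fs))
                       for f in freqs)
        idx = np.arange(max_half, len(times) - max_half)
        if len(idx) == 0:
            raise ValueError("epoch too short for the requested wavelets")
    else:
        idx = _output_slice(times, fs, freqs, *output_window_s)
    out = np.empty(data.shape[:2] + (len(freqs), len(idx)), complex)
    for k, f in enumerate(freqs):
        kern = morlet_kernel(f, fs)
        conv = fftconvolve(data, kern[None, None, :], mode="same", axes=2)
        out[:, :, k, :] = conv[:, :, idx]
    coeffs = out[0] if single else out
    return coeffs, times[idx]


def itc(coefficients: np.ndarray, times: np.ndarray, freqs,
        channel_labels) -> TFResult:
    """Inter-trial coherence: mean resultant length of trial phases.

    Zero-magnitude coefficients have undefined phase and are excluded at
    that point (count recorded).
    """
    c = np.asarray(coefficients)
    if c.shape[0] < 2:
        raise ValueError("ITC needs at least 2 trials")
    mag = np.abs(c)
    valid = mag > 0
    unit = np.where(valid, c / np.where(valid, mag, 1.0), 0.0)
    n_valid = valid.sum(axis=0)
    n_excluded = int((~valid).sum())
    with np.errstate(invalid="ignore"):
        vals = np.abs(unit.sum(axis=0)) / np.maximum(n_valid, 1)
    vals[n_valid == 0] = 0.0
    return TFResult("itc", vals, np.asarray(freqs, float), times,
                    tuple(channel_labels), c.shape[0], n_excluded)


def _baseline_mask(times: np.ndarray) -> np.ndarray:
    lo, hi = np.asarray(ASSR_BASELINE_MS) / 1000.0
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside time axis")
    return mask


def total_power(coefficients: np.ndarray, times: np.ndarray, freqs,
                channel_labels) -> TFResult:
    """Trial-mean |c|^2, 10log10, then per-frequency baseline-mean subtraction."""
    c = np.asarray(coefficients)
    power = np.mean(np.abs(c) ** 2, axis=0)
    power = np.maximum(power, POWER_FLOOR)
    db = 10.0 * np.log10(power)
    base = db[:, :, _baseline_mask(times)].mean(axis=2, keepdims=True)
    return TFResult("total_power_db", db - base, np.asarray(freqs, float),
                    times, tuple(channel_labels), c.shape[0])


def evoked_power(avg_coefficients: np.ndarray, times: np.ndarray, freqs,
                 channel_labels, n_trials: int = 1) -> TFResult:
    """|c|^2 of the trial-average waveform, baseline subtracted (linear units)."""
    power = np.abs(np.asarray(avg_coefficients)) ** 2
    base = power[:, :, _baseline_mask(times)].mean(axis=2, keepdims=True)
    return TFResult("evoked_power", power - base, np.asarray(freqs, float),
                    times, tuple(channel_labels), n_trials)


def assr_time_frequency(epochs: EpochSet, freqs=ASSR_FREQS,
                        output_window_ms=ASSR_OUTPUT_WINDOW_MS,
                        channels: list[str] | None = None
                        ) -> dict[str, TFResult]:
    """ITC, baseline-corrected total power (dB), and evoked power for the
    click-train epochs, computed frequency-by-frequency (memory-bounded)."""
    surv = np.nonzero(epochs.surviving)[0]
    if len(surv) < 2:
        raise ValueError("need at least 2 surviving trials")
    if channels is None:
        ch_idx = list(range(len(epochs.channel_labels)))
        labels = epochs.channel_labels
    else:
        ch_idx = [epochs.channel_index(c) for c in channels]
        labels = tuple(channels)
    data = epochs.data[np.ix_(surv, ch_idx)]
    avg = data.mean(axis=0)
    fs = epochs.sampling_rate
    freqs = np.atleast_1d(np.asarray(freqs, float))
    tmin, tmax = np.asarray(output_window_ms) / 1000.0
    idx = _output_slice(epochs.times, fs, freqs, tmin, tmax)
    out_times = epochs.times[idx]
    n_tr, n_ch, n_t = data.shape[0], len(ch_idx), len(idx)

    itc_vals = np.empty((n_ch, len(freqs), n_t))
    tot_vals = np.empty_like(itc_vals)
    ev_vals = np.empty_like(itc_vals)
    for k, f in enumerate(freqs):
        kern = morlet_kernel(f, fs)
        c = fftconvolve(data, kern[None, None, :], mode="same", axes=2)[:, :, idx]
        mag = np.abs(c)
        valid = mag > 0
        unit = np.where(valid, c / np.where(valid, mag, 1.0), 0.0)
        n_valid = np.maximum(valid.sum(axis=0), 1)
        itc_vals[:, k, :] = np.abs(unit.sum(axis=0)) / n_valid
        tot_vals[:, k, :] = 10.0 * np.log10(np.maximum((mag ** 2).mean(axis=0),
                                                       POWER_FLOOR))
        c_avg = fftconvolve(avg, kern[None, :], mode="same", axes=1)[:, idx]
        ev_vals[:, k, :] = np.abs(c_avg) ** 2

    bmask = _baseline_mask(out_times)
    tot_vals -= tot_vals[:, :, bmask].mean(axis=2, keepdims=True)
    ev_vals -= ev_vals[:, :, bmask].mean(axis=2, keepdims=True)
    return {
        "assr_itc": TFResult("itc", itc_vals, freqs, out_times, labels, n_tr),
        "assr_total": TFResult("total_power_db", tot_vals, freqs, out_times,
                               labels, n_tr),
        "assr_evoked": TFResult("evoked_power", ev_vals, freqs, out_times,
                                labels, n_tr),
    }


def extract_assr_measures(tf_results: dict[str, TFResult],
                          clusters: dict[str, tuple[str, ...]] | None = None,
                          meta=None) -> pd.DataFrame:
    """Mean over 100-500 ms, the 38/40/42 Hz bins, and the measure's cluster."""
    clusters = clusters or ASSR_CLUSTERS
    lo, hi = np.asarray(ASSR_MEASURE_WINDOW_MS) / 1000.0
    rows = []
    for name, tf in tf_results.items():
        cluster = clusters[name]
        missing = [c for c in cluster if c not in tf.channel_labels]
        if missing:
            raise ValueError(f"cluster channels missing: {missing}")
        ci = [tf.channel_labels.index(c) for c in cluster]
        fi = [int(np.nonzero(np.isclose(tf.frequency_axis, f))[0][0])
              for f in ASSR_MEASURE_BINS]
        ti = np.nonzero((tf.time_axis >= lo - 1e-9) & (tf.time_axis <= hi + 1e-9))[0]
        val = float(tf.values[np.ix_(ci, fi, ti)].mean())
        rows.append(dict(subject_id=getattr(meta, "subject_id", "unknown"),
                         group=getattr(meta, "group", "CON"),
                         occasion=getattr(meta, "occasion", "baseline"),
                         run_index="all", measure_name=name, value=val))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
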