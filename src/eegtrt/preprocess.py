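"""ERP and resting-state preprocessing chains.

The ERP chain is fixed in this order: 0.2 Hz high-pass -> downsample to
250 Hz -> bad-channel detection/interpolation -> robust common average
reference (excluding mastoids and Fp1/Fp2 from the reference mean) ->
epoching -> BSS-CCA muscle separation -> z >= 3 outlier-epoch rejection ->
ocular proxy regression -> baseline correction. Every stage is a pure
function of its inputs, so re-running a pipeline is bit-identical.

Ocular cleaning is a deterministic regression on an Fp1/Fp2 blink proxy
(band-passed 0.5-8 Hz, coefficients fitted on blink-detected segments);
muscle separation is a canonical correlation analysis between the data and
its one-sample delay, discarding weakly autocorrelated, high-frequency
sources.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, signal

from .core import EventTable, Montage, RawSession

__all__ = [
    "EpochSet",
    "PreprocReport",
    "highpass_filter",
    "downsample",
    "detect_bad_channels",
    "interpolate_channels",
    "robust_average_reference",
    "epoch",
    "reject_epochs_faster",
    "bsscca_muscle_removal",
    "remove_ocular",
    "baseline_correct",
    "resting_preprocess",
    "erp_preprocess",
]

#: channels never contributing to the reference mean (mastoids + frontopolar)
REFERENCE_EXCLUDE = ("TP9", "TP10", "Fp1", "Fp2")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: (epochs, channels, time) in microvolts."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to event onset
    sampling_rate: float
    channel_labels: tuple[str, ...]
    conditions: np.ndarray  # per epoch
    run_indices: np.ndarray  # per epoch, 1-based
    rejected: np.ndarray  # bool per epoch
    reject_reason: list
    reference_state: str = "FCz"
    montage: Montage | None = None

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def surviving(self) -> np.ndarray:
        return ~self.rejected

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), rejected=self.rejected.copy(),
                       reject_reason=list(self.reject_reason))


@dataclass
class PreprocReport:
    bad_channels: list = field(default_factory=list)
    bad_channel_criteria: dict = field(default_factory=dict)
    n_epochs_rejected: dict = field(default_factory=dict)
    n_cca_components_removed: int = 0
    n_ocular_components_removed: int = 0
    line_noise_power: dict = field(default_factory=dict)
    reference_converged: bool = True
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Filtering / resampling
# ---------------------------------------------------------------------------

def highpass_filter(raw: RawSession, cutoff_hz: float) -> RawSession:
    """Zero-phase 4th-order Butterworth high-pass (forward-backward)."""
    nyq = raw.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=raw.sampling_rate,
                        output="sos")
    data = raw.data - raw.data.mean(axis=1, keepdims=True)
    # long pad: the impulse response of a sub-hertz high-pass spans seconds
    padlen = int(min(raw.n_samples - 1, 3 * raw.sampling_rate / cutoff_hz))
    data = signal.sosfiltfilt(sos, data, axis=1, padlen=padlen)
    return replace(raw, data=data)


def downsample(raw: RawSession, target_hz: float = 250.0) -> RawSession:
    """Anti-alias (8th-order low-pass at 0.4 x target) then decimate.

    Event onsets are stored in seconds, so they carry over to the new clock
    unchanged.
    """
    q = raw.sampling_rate / target_hz
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"target {target_hz} Hz does not divide {raw.sampling_rate} Hz")
    q = int(round(q))
    if q == 1:
        return raw.copy()
    sos = signal.butter(8, 0.4 * target_hz, btype="lowpass",
                        fs=raw.sampling_rate, output="sos")
    data = signal.sosfiltfilt(sos, raw.data, axis=1)[:, ::q]
    return replace(raw, data=data, sampling_rate=float(target_hz))


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    return (x - med) / mad


def detect_bad_channels(raw_or_data, montage: Montage | None = None, *,
                        amplitude_z: float = 5.0, correlation_min: float = 0.4,
                        noise_z: float = 5.0, n_neighbors: int = 8,
                        sampling_rate: float | None = None,
                        exclude: tuple[str, ...] = ()) -> list[str]:
    """Flag outlier channels by robust amplitude deviation, low correlation
    with spatial neighbors, and high-frequency noisiness.

    Requires at least 8 channels. A flat channel has undefined neighbor
    correlation, which is treated as zero and therefore flagged.
    """
    if isinstance(raw_or_data, RawSession):
        data, montage = raw_or_data.data, raw_or_data.montage
        fs = raw_or_data.sampling_rate
    else:
        data = np.asarray(raw_or_data)
        fs = sampling_rate or 250.0
        if montage is None:
            raise ValueError("montage required when passing a bare array")
    labels = montage.channel_labels[: data.shape[0]]
    if len(labels) < 8:
        raise ValueError("need at least 8 channels")
    # subsample long recordings for speed
    stride = max(1, data.shape[1] // 100_000)
    x = data[:, ::stride]
    candidates = [i for i, lb in enumerate(labels) if lb not in exclude]

    # robust amplitude deviation
    amp = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    z_amp = _robust_z(amp[candidates])

    # correlation with spatial neighbors
    pos = montage.position_array(labels)
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xn = xc / sd_safe[:, None]
    corr = (xn @ xn.T) / x.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    max_neighbor_corr = np.zeros(len(labels))
    for i in range(len(labels)):
        d = np.linalg.norm(pos - pos[i], axis=1)
        order = np.argsort(d)[1: n_neighbors + 1]
        max_neighbor_corr[i] = np.max(np.abs(corr[i, order])) if sd[i] > 0 else 0.0

    # high-frequency noisiness: power fraction above 0.4 x Nyquist
    freqs, psd = signal.welch(x, fs=fs / stride if stride > 1 else fs,
                              nperseg=min(512, x.shape[1]), axis=1)
    hf = freqs > 0.4 * freqs.max()
    tot = psd.sum(axis=1)
    tot[tot == 0] = 1.0
    hf_frac = psd[:, hf].sum(axis=1) / tot
    z_noise = _robust_z(hf_frac[candidates])

    bads = set()
    crit = {}
    for k, i in enumerate(candidates):
        lb = labels[i]
        if abs(z_amp[k]) > amplitude_z:
            bads.add(lb)
            crit[lb] = "amplitude"
        if max_neighbor_corr[i] < correlation_min:
            bads.add(lb)
            crit.setdefault(lb, "correlation")
        if z_noise[k] > noise_z:
            bads.add(lb)
            crit.setdefault(lb, "noisiness")
    return sorted(bads, key=labels.index)


# ---------------------------------------------------------------------------
# Spherical spline interpolation (Perrin et al. style)
# ---------------------------------------------------------------------------

def _spline_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness) / (4 * np.pi)
    return np.polynomial.legendre.legval(np.clip(cosang, -1, 1),
                                         np.concatenate([[0.0], coef]))


def spline_interpolation_matrix(pos_good: np.ndarray, pos_bad: np.ndarray,
                                reg: float = 1e-5) -> np.ndarray:
    """Matrix M with x_bad = M @ x_good under a spherical-spline model."""
    g_gg = _spline_g(pos_good @ pos_good.T)
    g_bg = _spline_g(pos_bad @ pos_good.T)
    n_g = len(pos_good)
    A = np.empty((n_g + 1, n_g + 1))
    A[:n_g, :n_g] = g_gg + reg * np.eye(n_g)
    A[:n_g, n_g] = 1.0
    A[n_g, :n_g] = 1.0
    A[n_g, n_g] = 0.0
    Ainv = linalg.inv(A)
    # x_bad = [g_bg, 1] @ Ainv[:, :n_g] @ x_good  (c0 row included)
    B = np.hstack([g_bg, np.ones((len(pos_bad), 1))])
    return B @ Ainv[:, :n_g]


def interpolate_channels(raw: RawSession, labels: list[str]) -> RawSession:
    """Replace the given channels by spherical-spline estimates from the rest."""
    if not labels:
        return raw.copy()
    chs = raw.montage.channel_labels
    unknown = [lb for lb in labels if lb not in chs]
    if unknown:
        raise ValueError(f"labels not in montage: {unknown}")
    bad_idx = [chs.index(lb) for lb in labels]
    good_idx = [i for i in range(len(chs)) if i not in bad_idx]
    if len(good_idx) < 4:
        raise ValueError("fewer than 4 good channels remain")
    pos = raw.montage.position_array(chs)
    M = spline_interpolation_matrix(pos[good_idx], pos[bad_idx])
    data = raw.data.copy()
    data[bad_idx] = M @ data[good_idx]
    return replace(raw, data=data)


# ---------------------------------------------------------------------------
# Robust common average reference
# ---------------------------------------------------------------------------

def robust_average_reference(raw: RawSession,
                             exclude: tuple[str, ...] = REFERENCE_EXCLUDE,
                             initial_bads: list[str] | None = None,
                             max_iter: int = 10,
                             interpolate_bads: bool = True,
                             detect: bool = True) -> RawSession:
    """Iteratively estimated common average reference.

    The reference is the mean over channels that are neither excluded nor
    detected as bad; bad channels are re-detected against each interim
    reference until the set stabilizes (at most ``max_iter`` rounds). The
    final reference is subtracted from *all* channels, including excluded
    ones; the online FCz reference is first reconstructed as an explicit
    (zero) channel so it remains scorable afterwards. Detected bad channels
    are spline-interpolated before the final subtraction.
    """
    sess = raw.with_reference_channel()
    labels = sess.montage.channel_labels
    bads = set(initial_bads or [])
    converged = not detect
    for _ in range(max_iter if detect else 0):
        included = [i for i, lb in enumerate(labels)
                    if lb not in exclude and lb not in bads]
        ref = sess.data[included].mean(axis=0)
        new_bads = set(detect_bad_channels(
            sess.data - ref[None, :], sess.montage,
            sampling_rate=sess.sampling_rate, exclude=exclude))
        if new_bads == bads:
            converged = True
            break
        bads = new_bads
    if not converged:
        warnings.warn("robust reference did not converge; using last iterate")
    if bads and interpolate_bads:
        # repaired channels rejoin the reference set
        sess = interpolate_channels(sess, sorted(bads, key=labels.index))
        bads = set()
    included = [i for i, lb in enumerate(labels)
                if lb not in exclude and lb not in bads]
    ref = sess.data[included].mean(axis=0)
    data = sess.data - ref[None, :]
    return replace(sess, data=data)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(raw: RawSession, events: EventTable,
          window: tuple[float, float]) -> EpochSet:
    """Cut stimulus-locked epochs over the half-open window [start, end) s.

    Events whose epoch would extend past the recording edges are dropped with
    a warning.
    """
    start, end = window
    if not (start <= 0.0 < end):
        raise ValueError("window must bracket time 0")
    if len(events) == 0:
        raise ValueError("empty event selection")
    fs = raw.sampling_rate
    off0 = int(round(start * fs))
    n_t = int(round((end - start) * fs))
    times = (off0 + np.arange(n_t)) / fs

    keep_rows, slices = [], []
    for k, onset in enumerate(events.onsets):
        i_on = int(round(onset * fs))
        a = i_on + off0
        if a < 0 or a + n_t > raw.n_samples:
            continue
        keep_rows.append(k)
        slices.append(a)
    n_drop = len(events) - len(keep_rows)
    if n_drop:
        warnings.warn(f"{n_drop} events too close to recording edges dropped")
    if not keep_rows:
        raise ValueError("no epochs fit within the recording")
    data = np.stack([raw.data[:, a:a + n_t] for a in slices])
    edf = events.df.iloc[keep_rows]
    ref_state = ("average" if raw.montage.reference_label in raw.montage.channel_labels
                 else raw.montage.reference_label)
    return EpochSet(
        data=data, times=times, sampling_rate=fs,
        channel_labels=raw.montage.channel_labels,
        conditions=edf["condition"].to_numpy(object),
        run_indices=edf["run_index"].to_numpy(int),
        rejected=np.zeros(len(keep_rows), bool),
        reject_reason=[None] * len(keep_rows),
        reference_state=ref_state, montage=raw.montage,
    )


# ---------------------------------------------------------------------------
# FASTER-style epoch rejection
# ---------------------------------------------------------------------------

def _z_or_zero(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)  # degenerate spread: reject nothing
    return (x - x.mean()) / sd


def faster_epoch_stats(data: np.ndarray) -> dict[str, np.ndarray]:
    """Per-epoch channel-mean statistics: mean amplitude, mean variance, and
    mean peak-to-peak voltage."""
    return {
        "mean_amplitude": data.mean(axis=(1, 2)),
        "mean_variance": data.var(axis=2).mean(axis=1),
        "mean_ptp": (data.max(axis=2) - data.min(axis=2)).mean(axis=1),
    }


def reject_epochs_faster(epochs: EpochSet, z_thresh: float = 3.0,
                         channel_subset: list[str] | None = None) -> EpochSet:
    """Reject epochs |z| >= 3 on any of the three channel-mean statistics.

    Statistics are z-scored across epochs once (no re-iteration); zero spread
    defines zero z-scores, so identical epochs are never rejected.
    """
    if epochs.n_epochs < 3:
        raise ValueError("need at least 3 epochs")
    out = epochs.copy()
    data = out.data
    if channel_subset is not None:
        idx = [out.channel_index(lb) for lb in channel_subset]
        data = data[:, idx, :]
    for name, stat in faster_epoch_stats(data).items():
        z = _z_or_zero(stat)
        for i in np.nonzero(np.abs(z) >= z_thresh)[0]:
            if not out.rejected[i]:
                out.rejected[i] = True
                out.reject_reason[i] = f"faster:{name}"
    return out


# ---------------------------------------------------------------------------
# BSS-CCA muscle separation
# ---------------------------------------------------------------------------

def bsscca_muscle_removal(epochs: EpochSet, autocorr_max: float = 0.6,
                          hf_fraction_min: float = 0.5,
                          hf_cutoff_hz: float = 30.0
                          ) -> tuple[EpochSet, PreprocReport]:
    """Blind source separation by CCA between the data and its 1-sample delay.

    Sources are ordered by canonical correlation, which equals their lag-1
    autocorrelation. Sources that are both weakly autocorrelated
    (rho < ``autocorr_max``) and dominated by power above ``hf_cutoff_hz``
    (fraction > ``hf_fraction_min``) are discarded; the data are
    reconstructed from the remaining sources.
    """
    report = PreprocReport()
    surv = np.nonzero(epochs.surviving)[0]
    X = epochs.data[surv]  # (n_ep, ch, t)
    n_ep, n_ch, n_t = X.shape
    mean = X.mean(axis=(0, 2), keepdims=False).reshape(1, n_ch, 1)
    Xc = X - mean

    # lagged covariances accumulated within epochs (no cross-epoch products)
    C0 = np.zeros((n_ch, n_ch))
    C1 = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        x = Xc[e]
        C0 += x @ x.T
        C1 += x[:, 1:] @ x[:, :-1].T
    C0 /= n_ep * n_t
    C1 /= n_ep * (n_t - 1)
    C1 = 0.5 * (C1 + C1.T)

    # guard against rank deficiency
    evals = linalg.eigvalsh(C0)
    if evals[0] < 1e-12 * evals[-1]:
        w, V = linalg.eigh(C0)
        keep = w > 1e-10 * w[-1]
        # one lost dimension is expected after average referencing
        if (~keep).sum() > 1:
            warnings.warn("rank-deficient data; reducing dimensionality")
        P = V[:, keep]
        rho, Wr = linalg.eigh(P.T @ C1 @ P, P.T @ C0 @ P)
        W = P @ Wr
    else:
        rho, W = linalg.eigh(C1, C0)
    order = np.argsort(rho)[::-1]
    rho, W = rho[order], W[:, order]  # descending autocorrelation
    # C0-orthonormal: W.T C0 W = I, so the mixing matrix is A = C0 W
    A = C0 @ W

    # source spectra from concatenated epochs
    S = np.einsum("cs,ect->est", W, Xc)
    S_flat = np.concatenate(list(S), axis=1)
    freqs, psd = signal.welch(S_flat, fs=epochs.sampling_rate,
                              nperseg=min(256, n_t), axis=1)
    tot = psd.sum(axis=1)
    tot[tot == 0] = 1.0
    hf_frac = psd[:, freqs > hf_cutoff_hz].sum(axis=1) / tot

    remove = (rho < autocorr_max) & (hf_frac > hf_fraction_min)
    report.n_cca_components_removed = int(remove.sum())
    report.notes.append({"cca_autocorr": rho.tolist()})

    out = epochs.copy()
    if remove.any():
        keep = ~remove
        T = A[:, keep] @ W[:, keep].T  # projection in sensor space
        out.data[surv] = mean + np.einsum("cd,edt->ect", T, Xc)
    return out, report


# ---------------------------------------------------------------------------
# Ocular proxy regression
# ---------------------------------------------------------------------------

def remove_ocular(epochs: EpochSet, blink_z: float = 5.0,
                  band=(0.5, 8.0)) -> tuple[EpochSet, PreprocReport]:
    """Regress out an Fp1/Fp2 blink proxy from all channels.

    The proxy is the Fp1/Fp2 mean band-passed 0.5-8 Hz (filtered across the
    concatenated epochs so sub-second blinks are not distorted by epoch
    boundaries); regression coefficients are fitted on blink-detected samples
    only (|proxy| above ``blink_z`` robust SDs), so blink-free data are
    essentially untouched.
    """
    report = PreprocReport()
    for lb in ("Fp1", "Fp2"):
        if lb not in epochs.channel_labels:
            raise ValueError(f"proxy channel {lb} missing")
    i1, i2 = epochs.channel_index("Fp1"), epochs.channel_index("Fp2")
    out = epochs.copy()
    surv = np.nonzero(out.surviving)[0]
    X = out.data[surv]
    n_t = X.shape[2]
    proxy = 0.5 * (X[:, i1, :] + X[:, i2, :])
    nyq = epochs.sampling_rate / 2
    sos = signal.butter(4, [band[0], min(band[1], 0.95 * nyq)],
                        btype="bandpass", fs=epochs.sampling_rate, output="sos")
    proxy = signal.sosfiltfilt(sos, proxy.reshape(-1)).reshape(-1, n_t)

    flat = proxy.ravel()
    med = np.median(flat)
    mad = np.median(np.abs(flat - med)) * 1.4826
    if mad == 0:
        return out, report
    blink_mask = np.abs(flat - med) > blink_z * mad
    if blink_mask.sum() < 10:
        return out, report

    p = flat[blink_mask] - med
    pc = p - p.mean()
    var_p = float(pc @ pc)
    if var_p == 0:
        return out, report
    Xf = X.transpose(1, 0, 2).reshape(X.shape[1], -1)
    seg = Xf[:, blink_mask]
    beta = (seg - seg.mean(axis=1, keepdims=True)) @ pc / var_p
    out.data[surv] = X - beta[None, :, None] * (proxy - med)[:, None, :]
    report.n_ocular_components_removed = 1
    report.notes.append({"ocular_beta_max": float(np.abs(beta).max())})
    return out, report


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.1, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over [start, end) s."""
    t = epochs.times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Full chains
# ---------------------------------------------------------------------------

def erp_preprocess(raw: RawSession, events: EventTable,
                   window: tuple[float, float],
                   baseline: tuple[float, float] | None = (-0.1, 0.0),
                   *, clean_artifacts: bool = True, detect_bads: bool = True
                   ) -> tuple[EpochSet, PreprocReport]:
    """The full ERP chain on one paradigm segment, returning clean epochs.

    ``clean_artifacts``/``detect_bads`` switch off the data-driven stages for
    controlled signal-path experiments; the filtering, referencing, epoching,
    and scoring path is unchanged.
    """
    report = PreprocReport()
    x = highpass_filter(raw, 0.2)
    x = downsample(x, 250.0)
    bads = detect_bad_channels(x, exclude=REFERENCE_EXCLUDE) if detect_bads else []
    report.bad_channels = bads
    if bads:
        x = interpolate_channels(x, bads)
    x = robust_average_reference(x, initial_bads=bads, detect=detect_bads)
    eps = epoch(x, events, window)
    if clean_artifacts:
        eps, cca_rep = bsscca_muscle_removal(eps)
        report.n_cca_components_removed = cca_rep.n_cca_components_removed
    eps = reject_epochs_faster(eps)
    report.n_epochs_rejected = {"faster": int(eps.rejected.sum())}
    if clean_artifacts:
        eps, oc_rep = remove_ocular(eps)
        report.n_ocular_components_removed = oc_rep.n_ocular_components_removed
    if baseline is not None:
        eps = baseline_correct(eps, baseline)
    return eps, report


def resting_preprocess(raw: RawSession, n_epochs: int = 180
                       ) -> tuple[EpochSet, PreprocReport]:
    """Resting chain: 0.5 Hz high-pass, 250 Hz downsample, common average,
    bad-channel detection, first ``n_epochs`` whole-second epochs, outlier
    rejection from clean channels, conservative ocular/muscle cleaning,
    interpolation of bads, final common average."""
    if raw.duration < n_epochs:
        raise ValueError(f"rest run shorter than {n_epochs} s")
    report = PreprocReport()
    x = highpass_filter(raw, 0.5)
    x = downsample(x, 250.0)
    x = x.with_reference_channel()
    x = replace(x, data=x.data - x.data.mean(axis=0, keepdims=True))
    bads = detect_bad_channels(x)
    report.bad_channels = bads

    import pandas as pd
    from .core import EVENT_COLUMNS
    onsets = np.arange(n_epochs, dtype=float)
    ev = EventTable(pd.DataFrame({
        "onset": onsets, "code": "rest", "modality": "auditory",
        "condition": "rest", "run_index": 1,
        "paradigm": raw.events.df["paradigm"].iloc[0] if len(raw.events) else "rest_open",
    })[EVENT_COLUMNS], validate=False)
    eps = epoch(x, ev, (0.0, 1.0))
    good = [lb for lb in eps.channel_labels if lb not in bads]
    if len(good) < 4:
        raise ValueError(f"only {len(good)} clean channels; data unusable")
    eps = reject_epochs_faster(eps, channel_subset=good)
    report.n_epochs_rejected = {"faster": int(eps.rejected.sum())}
    eps, oc_rep = remove_ocular(eps, blink_z=4.0)
    eps, cca_rep = bsscca_muscle_removal(eps, autocorr_max=0.5,
                                         hf_fraction_min=0.6)
    report.n_ocular_components_removed = oc_rep.n_ocular_components_removed
    report.n_cca_components_removed = cca_rep.n_cca_components_removed
    if bads:
        pos = eps.montage.position_array(eps.channel_labels)
        bad_idx = [eps.channel_index(lb) for lb in bads]
        good_idx = [i for i in range(len(eps.channel_labels)) if i not in bad_idx]
        M = spline_interpolation_matrix(pos[good_idx], pos[bad_idx])
        eps.data[:, bad_idx, :] = np.einsum("bg,egt->ebt", M, eps.data[:, good_idx, :])
    eps.data -= eps.data.mean(axis=1, keepdims=True)  # final common average
    eps.reference_state = "average"
    return eps, report
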