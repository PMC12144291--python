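"""Resting-state power spectral density and band power extraction.

PSDs are Hamming-tapered per-epoch periodograms averaged over the surviving
1-second epochs (Welch with non-overlapping 1 s segments), density-scaled so
that the integral over frequency approximates the signal variance. Band
power is the mean density across a band's integer-frequency bins, averaged
over the band's electrode cluster ("absolute power").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import MEASURE_COLUMNS
from .preprocess import EpochSet

__all__ = ["PSDResult", "BandDefinition", "BANDS", "compute_psd", "band_power",
           "rest_band_measures", "psd_to_frame"]


@dataclass
class PSDResult:
    values: np.ndarray  # channels x frequency, uV^2/Hz
    frequency_axis: np.ndarray  # 0..fs/2 at 1 Hz resolution (1-s epochs)
    channel_labels: tuple[str, ...]
    condition: str  # eyes_open | eyes_closed
    n_epochs_used: int

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float  # inclusive integer bins
    f_high: float
    cluster: tuple[str, ...]


#: conventional band limits with the clusters where each band is most prominent
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1, 3, ("Fz", "FCz")),
    "theta": BandDefinition("theta", 4, 7, ("Fz", "FCz")),
    "alpha": BandDefinition("alpha", 8, 12, ("Pz", "P1", "P2", "POz", "PO3", "PO4")),
    "beta": BandDefinition("beta", 13, 30,
                           ("AF3", "AF4", "F3", "F4", "F5", "F6", "POz", "PO3", "PO4")),
    "gamma": BandDefinition("gamma", 31, 48,
                            ("AFz", "AF3", "AF4", "Fz", "F3", "F4", "F5", "F6")),
}


def compute_psd(epochs: EpochSet, condition: str = "eyes_open",
                min_epochs: int = 10) -> PSDResult:
    """Average Hamming-tapered periodogram over surviving epochs."""
    surv = np.nonzero(epochs.surviving)[0]
    if len(surv) < min_epochs:
        raise ValueError(f"need at least {min_epochs} surviving epochs")
    data = epochs.data[surv]
    freqs, psd = signal.periodogram(data, fs=epochs.sampling_rate,
                                    window="hamming", scaling="density", axis=2)
    return PSDResult(values=psd.mean(axis=0), frequency_axis=freqs,
                     channel_labels=epochs.channel_labels,
                     condition=condition, n_epochs_used=len(surv))


def band_power(psd: PSDResult, band: BandDefinition) -> float:
    """Mean density over the band's integer bins, then over its cluster."""
    missing = [c for c in band.cluster if c not in psd.channel_labels]
    if missing:
        raise ValueError(f"cluster electrodes missing: {missing}")
    mask = (psd.frequency_axis >= band.f_low - 1e-9) & \
           (psd.frequency_axis <= band.f_high + 1e-9)
    if not mask.any():
        raise ValueError("band outside frequency axis")
    idx = [psd.channel_labels.index(c) for c in band.cluster]
    return float(psd.values[np.ix_(idx, np.nonzero(mask)[0])].mean())


def psd_to_frame(psd: PSDResult) -> pd.DataFrame:
    """Channel x frequency density table (columns are frequencies in Hz),
    suitable for TSV export."""
    return pd.DataFrame(psd.values, index=list(psd.channel_labels),
                        columns=[f"{f:g}" for f in psd.frequency_axis])


def rest_band_measures(psd: PSDResult, condition: str, meta=None) -> pd.DataFrame:
    """One measure-table row per band for one rest condition."""
    tag = "open" if "open" in condition else "closed"
    rows = [dict(subject_id=getattr(meta, "subject_id", "unknown"),
                 group=getattr(meta, "group", "CON"),
                 occasion=getattr(meta, "occasion", "baseline"),
                 run_index="all", measure_name=f"rest_{tag}_{name}",
                 value=band_power(psd, band))
            for name, band in BANDS.items()]
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
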