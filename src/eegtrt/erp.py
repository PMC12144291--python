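"""ERP averaging, difference waves, peak finding, and component scoring.

Components are scored on condition-difference waves (deviant-standard for
the mismatch negativity, target-standard and novel-standard for the P3b and
P3a) as the average amplitude in a +/- 40 ms window centered on the
component's grand-average peak, averaged over a small electrode cluster
where the component is most prominent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MEASURE_COLUMNS
from .preprocess import EpochSet

__all__ = [
    "ERPWave",
    "ComponentDefinition",
    "DEFAULT_COMPONENTS",
    "default_component_definitions",
    "average_erp",
    "difference_wave",
    "find_component_peak",
    "score_component",
    "score_by_run",
    "derive_windows_from_grand_average",
]


@dataclass
class ERPWave:
    data: np.ndarray  # channels x time, microvolts
    times: np.ndarray  # seconds
    channel_labels: tuple[str, ...]
    condition: str
    n_epochs_averaged: int

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True)
class ComponentDefinition:
    """Where and how a component is scored.

    ``score_window_ms`` is peak latency +/- 40 ms; the score is the mean over
    window samples (sample centers within the closed interval) then over the
    cluster electrodes.
    """

    name: str
    polarity: int  # +1 or -1
    search_window_ms: tuple[float, float]
    peak_latency_ms: float
    peak_electrode: str
    cluster: tuple[str, ...]
    minuend: str  # condition of the difference-wave minuend
    subtrahend: str = "standard"

    @property
    def score_window_ms(self) -> tuple[float, float]:
        return (self.peak_latency_ms - 40.0, self.peak_latency_ms + 40.0)


def default_component_definitions() -> list[ComponentDefinition]:
    """The five scored ERP components with their fixed windows and clusters."""
    return [
        ComponentDefinition("mmn", -1, (100.0, 200.0), 126.0, "FCz",
                            ("Fz", "F1", "F2", "FCz", "FC1", "FC2"), "deviant"),
        ComponentDefinition("aod_p3b", +1, (250.0, 450.0), 339.0, "Pz",
                            ("CPz", "CP1", "CP2", "Pz", "P1", "P2"), "target"),
        ComponentDefinition("aod_p3a", +1, (250.0, 450.0), 316.0, "Cz",
                            ("FCz", "FC1", "FC2", "Cz", "C1", "C2"), "novel"),
        ComponentDefinition("vod_p3b", +1, (300.0, 550.0), 433.0, "Pz",
                            ("CPz", "CP1", "CP2", "Pz", "P1", "P2"), "target"),
        ComponentDefinition("vod_p3a", +1, (300.0, 500.0), 372.0, "CPz",
                            ("Cz", "C1", "C2", "CPz", "CP1", "CP2"), "novel"),
    ]


DEFAULT_COMPONENTS: dict[str, ComponentDefinition] = {
    c.name: c for c in default_component_definitions()
}


def average_erp(epochs: EpochSet, condition) -> ERPWave:
    """Arithmetic mean over surviving epochs of the given condition(s)."""
    conds = (condition,) if isinstance(condition, str) else tuple(condition)
    mask = epochs.surviving & np.isin(epochs.conditions, conds)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no surviving epochs of condition {condition!r}")
    return ERPWave(data=epochs.data[mask].mean(axis=0), times=epochs.times,
                   channel_labels=epochs.channel_labels,
                   condition="+".join(conds), n_epochs_averaged=n)


def difference_wave(a: ERPWave, b: ERPWave) -> ERPWave:
    """Pointwise a - b; time axes must match."""
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("time axes differ")
    if a.channel_labels != b.channel_labels:
        raise ValueError("channel sets differ")
    return ERPWave(data=a.data - b.data, times=a.times,
                   channel_labels=a.channel_labels,
                   condition=f"{a.condition}-{b.condition}",
                   n_epochs_averaged=min(a.n_epochs_averaged, b.n_epochs_averaged))


def find_component_peak(wave: ERPWave, polarity: int,
                        search_window_ms: tuple[float, float],
                        electrode: str) -> float:
    """Latency (ms) of the extremum of the given polarity within the window.

    Ties break toward the earliest latency. If no local extremum of the
    stated polarity exists the window-edge extremum is returned with a
    warning.
    """
    t_ms = wave.times * 1000.0
    mask = (t_ms >= search_window_ms[0]) & (t_ms <= search_window_ms[1])
    if not mask.any():
        raise ValueError("search window outside wave")
    x = wave.channel(electrode)[mask] * polarity
    tt = t_ms[mask]
    i = int(np.argmax(x))  # argmax returns the first (earliest) maximum
    interior = 0 < i < len(x) - 1
    if not interior:
        warnings.warn("no interior extremum of stated polarity; window edge returned")
    return float(tt[i])


def score_component(diff_wave: ERPWave, definition: ComponentDefinition) -> float:
    """Cluster-and-window mean amplitude (microvolts) of a difference wave.

    Samples whose centers lie in the closed window [peak-40, peak+40] ms are
    averaged, then averaged across the cluster electrodes.
    """
    missing = [c for c in definition.cluster if c not in diff_wave.channel_labels]
    if missing:
        raise ValueError(f"cluster electrodes missing: {missing}")
    t_ms = diff_wave.times * 1000.0
    lo, hi = definition.score_window_ms
    mask = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
    idx = [diff_wave.channel_labels.index(c) for c in definition.cluster]
    return float(diff_wave.data[np.ix_(idx, np.nonzero(mask)[0])].mean())


def score_by_run(epochs: EpochSet, definition: ComponentDefinition,
                 meta=None) -> pd.DataFrame:
    """Per-run difference-wave scores using the fixed session-level windows.

    Returns one measure-table row per run; runs lacking surviving epochs of
    either condition are flagged missing (NaN value).
    """
    rows = []
    for run in sorted(np.unique(epochs.run_indices)):
        run_mask = epochs.run_indices == run
        sub = EpochSet(
            data=epochs.data[run_mask], times=epochs.times,
            sampling_rate=epochs.sampling_rate,
            channel_labels=epochs.channel_labels,
            conditions=epochs.conditions[run_mask],
            run_indices=epochs.run_indices[run_mask],
            rejected=epochs.rejected[run_mask],
            reject_reason=[r for r, m in zip(epochs.reject_reason, run_mask) if m],
            reference_state=epochs.reference_state, montage=epochs.montage)
        try:
            w = difference_wave(average_erp(sub, definition.minuend),
                                average_erp(sub, definition.subtrahend))
            value = score_component(w, definition)
        except ValueError:
            value = np.nan
        rows.append(dict(
            subject_id=getattr(meta, "subject_id", "unknown"),
            group=getattr(meta, "group", "CON"),
            occasion=getattr(meta, "occasion", "baseline"),
            run_index=int(run), measure_name=definition.name, value=value))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def derive_windows_from_grand_average(grand_avg: ERPWave,
                                      definition: ComponentDefinition
                                      ) -> ComponentDefinition:
    """Re-center the +/- 40 ms score window on the grand-average peak.

    Provided for synthetic data whose kernels sit at other latencies; the
    default definitions keep the study's fixed windows.
    """
    lat = find_component_peak(grand_avg, definition.polarity,
                              definition.search_window_ms,
                              definition.peak_electrode)
    from dataclasses import replace as _replace
    return _replace(definition, peak_latency_ms=lat)
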