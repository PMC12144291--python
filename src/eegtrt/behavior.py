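"""Oddball task performance: miss rate, false-alarm rates, median reaction time.

A button press is attributed to the most recent stimulus whose response
window contains it (at most one response per stimulus); presses attributed
to non-target stimuli count as false alarms. The default window (100 to
1000 ms post-stimulus) sits below the minimum stimulus onset asynchrony of
both oddball tasks, so no press can be attributed twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MEASURE_COLUMNS, EventTable

__all__ = ["PerformanceResult", "score_performance", "performance_measures"]


@dataclass(frozen=True)
class PerformanceResult:
    miss_rate_targets: float  # percent
    fa_rate_novels: float  # percent
    fa_rate_standards: float  # percent
    median_rt_ms: float  # over correct targets; NaN if none
    n_targets: int
    n_novels: int
    n_standards: int
    n_hits: int
    n_fa_novels: int
    n_fa_standards: int


def score_performance(events: EventTable,
                      response_window: tuple[float, float] = (0.1, 1.0),
                      modality: str | None = None) -> PerformanceResult:
    """Score one task's event stream (stimuli + button presses)."""
    df = events.df
    stim = df[(df["modality"] != "response")
              & df["condition"].isin(["standard", "target", "novel"])]
    if modality is not None:
        stim = stim[stim["modality"] == modality]
    if (stim["condition"] == "target").sum() == 0:
        raise ValueError("no target stimuli in event stream")
    resp_on = np.sort(df.loc[df["modality"] == "response", "onset"].to_numpy(float))

    stim_on = stim["onset"].to_numpy(float)
    conds = stim["condition"].to_numpy(object)
    order = np.argsort(stim_on, kind="stable")
    stim_on, conds = stim_on[order], conds[order]

    lo, hi = response_window
    attributed = np.full(len(stim_on), np.nan)  # RT in s where a press landed
    used = np.zeros(len(resp_on), bool)
    for i, t in enumerate(resp_on):
        # most recent stimulus whose window contains this press
        j = np.searchsorted(stim_on, t - lo, side="right") - 1
        if j < 0:
            continue
        rt = t - stim_on[j]
        if lo <= rt <= hi and np.isnan(attributed[j]) and not used[i]:
            attributed[j] = rt
            used[i] = True

    is_t = conds == "target"
    is_n = conds == "novel"
    is_s = conds == "standard"
    hit = ~np.isnan(attributed)
    n_hits = int((hit & is_t).sum())
    n_fa_n = int((hit & is_n).sum())
    n_fa_s = int((hit & is_s).sum())
    rts = attributed[hit & is_t] * 1000.0
    return PerformanceResult(
        miss_rate_targets=100.0 * (is_t.sum() - n_hits) / is_t.sum(),
        fa_rate_novels=100.0 * n_fa_n / is_n.sum() if is_n.sum() else 0.0,
        fa_rate_standards=100.0 * n_fa_s / is_s.sum() if is_s.sum() else 0.0,
        median_rt_ms=float(np.median(rts)) if len(rts) else float("nan"),
        n_targets=int(is_t.sum()), n_novels=int(is_n.sum()),
        n_standards=int(is_s.sum()), n_hits=n_hits,
        n_fa_novels=n_fa_n, n_fa_standards=n_fa_s)


def performance_measures(events: EventTable, task: str, meta=None,
                         response_window=(0.1, 1.0)) -> pd.DataFrame:
    """Measure-table rows for one task: miss/FA rates and median RT."""
    modality = "visual" if task == "vod" else "auditory"
    perf = score_performance(events, response_window, modality=modality)
    vals = {
        f"{task}_miss_rate": perf.miss_rate_targets,
        f"{task}_fa_novel": perf.fa_rate_novels,
        f"{task}_fa_standard": perf.fa_rate_standards,
        f"{task}_median_rt": perf.median_rt_ms,
    }
    rows = [dict(subject_id=getattr(meta, "subject_id", "unknown"),
                 group=getattr(meta, "group", "CON"),
                 occasion=getattr(meta, "occasion", "baseline"),
                 run_index="all", measure_name=k, value=v)
            for k, v in vals.items()]
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
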