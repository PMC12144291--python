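"""Stimulus sequence generation for the five task paradigms.

The battery comprises an interleaved passive auditory oddball (mismatch
negativity) + visual oddball task, an active auditory oddball task, a 40-Hz
click-train steady-state paradigm, and eyes-open/eyes-closed rest:

* MMN: 90% standard tones (633 Hz, 50 ms) / 10% pitch+duration deviants
  (1000 Hz, 100 ms), 500 ms SOA, 3200 tones over 5 runs, each run opening
  with 20 standards.
* VOD: 80/10/10% standard/target/novel, 500 ms stimulus duration, SOA
  uniform 1.6-2.4 s on a 1/60 s grid, 800 stimuli over 5 runs, interleaved
  with the tones but never within 50 ms of a tone onset.
* AOD: 80/10/10%, SOA uniform 1.1-1.4 s in 25 ms steps, 800 stimuli over
  4 runs.
* ASSR: 150 click trains, 500 ms each (clicks every 25 ms -> 40 Hz),
  1.5 s SOA.
* Rest: 185 s eyes open, 185 s eyes closed.

"Pseudo-random" stimulus orders are constrained shuffles forbidding two
consecutive rare stimuli. All onsets are computed in integer milliseconds
(exactly representable at the 1000 Hz acquisition rate) and expressed in
seconds. Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, EventTable

__all__ = [
    "ParadigmSpec",
    "generate_mmn_vod_sequence",
    "generate_aod_sequence",
    "generate_assr_sequence",
    "session_schedule",
    "total_session_seconds",
]


@dataclass(frozen=True)
class ParadigmSpec:
    """Per-paradigm stimulus constants (defaults are the study's values)."""

    # MMN auditory stream
    mmn_standard_hz: float = 633.0
    mmn_standard_ms: float = 50.0
    mmn_deviant_hz: float = 1000.0
    mmn_deviant_ms: float = 100.0
    mmn_soa_ms: int = 500
    mmn_runs: int = 5
    mmn_tones_per_run: int = 640
    mmn_deviant_prop: float = 0.10
    mmn_leading_standards: int = 20

    # Visual oddball (interleaved with MMN)
    vod_runs: int = 5
    vod_stimuli_per_run: int = 160
    vod_target_prop: float = 0.10
    vod_novel_prop: float = 0.10
    vod_stim_ms: float = 500.0
    vod_soa_min_ms: float = 1600.0
    vod_soa_max_ms: float = 2400.0
    vod_soa_step_ms: float = 1000.0 / 60.0  # display-frame grid (60 Hz)
    cross_modal_sep_ms: float = 50.0

    # Auditory oddball
    aod_runs: int = 4
    aod_stimuli_per_run: int = 200
    aod_target_prop: float = 0.10
    aod_novel_prop: float = 0.10
    aod_soa_min_ms: int = 1100
    aod_soa_max_ms: int = 1400
    aod_soa_step_ms: int = 25

    # 40-Hz steady state
    assr_trains: int = 150
    assr_train_ms: int = 500
    assr_click_interval_ms: int = 25
    assr_soa_ms: int = 1500

    # rest
    rest_seconds: float = 185.0

    # layout
    run_lead_in_s: float = 1.0
    inter_run_gap_s: float = 10.0

    def __post_init__(self):
        assert abs(self.vod_target_prop + self.vod_novel_prop
                   + 0.8 - 1.0) < 1e-12
        assert self.mmn_deviant_prop <= 0.5


def _rng(seed: int) -> np.random.Generator:
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(int(seed))


def _nonadjacent_positions(n_slots: int, k: int, rng: np.random.Generator,
                           forbid_first: int = 0) -> np.ndarray:
    """Sample k slot indices from range(n_slots), no two adjacent, none in the
    first ``forbid_first`` slots."""
    avail = n_slots - forbid_first
    if k > (avail + 1) // 2:
        raise ValueError("cannot place rare stimuli without adjacency")
    # classic bijection: choose k from avail-k+1, then spread by offsets
    base = np.sort(rng.choice(avail - k + 1, size=k, replace=False))
    return base + np.arange(k) + forbid_first


def generate_mmn_vod_sequence(spec: ParadigmSpec = ParadigmSpec(),
                              seed: int = 0) -> EventTable:
    """Interleaved MMN tone stream and visual oddball sequence, five runs.

    Visual onsets are jittered on the 1/60 s grid and resampled until every
    visual onset is at least ``cross_modal_sep_ms`` away from every tone
    onset (tones sit on a fixed 500 ms lattice, so the constraint reduces to
    the onset phase within the tone cycle).
    """
    rng = _rng(seed)
    records: list[dict] = []
    run_start_ms = spec.run_lead_in_s * 1000.0

    n_dev = int(round(spec.mmn_tones_per_run * spec.mmn_deviant_prop))
    n_vt = int(round(spec.vod_stimuli_per_run * spec.vod_target_prop))
    n_vn = int(round(spec.vod_stimuli_per_run * spec.vod_novel_prop))
    sep = spec.cross_modal_sep_ms
    soa = spec.mmn_soa_ms

    for run in range(1, spec.mmn_runs + 1):
        # --- auditory stream: fixed lattice, constrained deviant placement
        dev_pos = _nonadjacent_positions(spec.mmn_tones_per_run, n_dev, rng,
                                         forbid_first=spec.mmn_leading_standards)
        is_dev = np.zeros(spec.mmn_tones_per_run, bool)
        is_dev[dev_pos] = True
        tone_on_ms = run_start_ms + soa * np.arange(spec.mmn_tones_per_run)
        for t, d in zip(tone_on_ms, is_dev):
            records.append(dict(
                onset=t / 1000.0, code="2" if d else "1", modality="auditory",
                condition="deviant" if d else "standard", run_index=run,
                paradigm="mmn_vod"))

        # --- visual stream: jittered SOAs with cross-modal separation
        rare_pos = _nonadjacent_positions(spec.vod_stimuli_per_run, n_vt + n_vn, rng)
        kinds = np.array(["standard"] * spec.vod_stimuli_per_run, dtype=object)
        rare_kinds = np.array(["target"] * n_vt + ["novel"] * n_vn, dtype=object)
        rng.shuffle(rare_kinds)
        kinds[rare_pos] = rare_kinds

        n_steps = int(round((spec.vod_soa_max_ms - spec.vod_soa_min_ms)
                            / spec.vod_soa_step_ms))
        t_ms = run_start_ms + float(rng.integers(200, 400))
        vis_on_ms = []
        for _ in range(spec.vod_stimuli_per_run):
            placed = False
            for _attempt in range(1000):
                step = int(rng.integers(0, n_steps + 1))
                cand = t_ms + spec.vod_soa_min_ms + step * spec.vod_soa_step_ms
                cand = float(round(cand))  # snap to 1 ms sample grid
                phase = (cand - run_start_ms) % soa
                if sep <= phase <= soa - sep:
                    vis_on_ms.append(cand)
                    t_ms = cand
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not satisfy cross-modal separation")
        code_of = {"standard": "11", "target": "12", "novel": "13"}
        for t, k in zip(vis_on_ms, kinds):
            records.append(dict(onset=t / 1000.0, code=code_of[k],
                                modality="visual", condition=k,
                                run_index=run, paradigm="mmn_vod"))
        run_start_ms += (soa * spec.mmn_tones_per_run
                         + spec.inter_run_gap_s * 1000.0)

    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    return EventTable(df)


def generate_aod_sequence(spec: ParadigmSpec = ParadigmSpec(),
                          seed: int = 0) -> EventTable:
    """Active auditory oddball sequence: four runs of 200 stimuli (160/20/20)."""
    rng = _rng(seed)
    records: list[dict] = []
    run_start_ms = spec.run_lead_in_s * 1000.0
    n_t = int(round(spec.aod_stimuli_per_run * spec.aod_target_prop))
    n_n = int(round(spec.aod_stimuli_per_run * spec.aod_novel_prop))
    n_steps = (spec.aod_soa_max_ms - spec.aod_soa_min_ms) // spec.aod_soa_step_ms

    for run in range(1, spec.aod_runs + 1):
        rare_pos = _nonadjacent_positions(spec.aod_stimuli_per_run, n_t + n_n, rng)
        kinds = np.array(["standard"] * spec.aod_stimuli_per_run, dtype=object)
        rare_kinds = np.array(["target"] * n_t + ["novel"] * n_n, dtype=object)
        rng.shuffle(rare_kinds)
        kinds[rare_pos] = rare_kinds

        soas = (spec.aod_soa_min_ms
                + spec.aod_soa_step_ms * rng.integers(0, n_steps + 1,
                                                      size=spec.aod_stimuli_per_run))
        on_ms = run_start_ms + np.concatenate([[0.0], np.cumsum(soas[:-1])])
        code_of = {"standard": "21", "target": "22", "novel": "23"}
        for t, k in zip(on_ms, kinds):
            records.append(dict(onset=t / 1000.0, code=code_of[k],
                                modality="auditory", condition=k,
                                run_index=run, paradigm="aod"))
        run_start_ms = on_ms[-1] + soas[-1] + spec.inter_run_gap_s * 1000.0

    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    return EventTable(df)


def generate_assr_sequence(spec: ParadigmSpec = ParadigmSpec(),
                           seed: int = 0) -> EventTable:
    """150 click-train onsets at a fixed 1.5 s SOA (single run).

    Each train implies 20 clicks at 25 ms spacing (a 40-Hz drive); only the
    train onsets are events.
    """
    start_ms = spec.run_lead_in_s * 1000.0 + 1500.0  # extra room for the long epoch
    on_ms = start_ms + spec.assr_soa_ms * np.arange(spec.assr_trains)
    records = [dict(onset=t / 1000.0, code="31", modality="click_train",
                    condition="train", run_index=1, paradigm="assr")
               for t in on_ms]
    return EventTable(pd.DataFrame.from_records(records, columns=EVENT_COLUMNS))


# ---------------------------------------------------------------------------
# Session schedule
# ---------------------------------------------------------------------------

#: (order, task, duration) in the fixed run order used at every site.
SESSION_SCHEDULE: tuple[tuple[int, str, str], ...] = (
    (1, "MMN/VOD Instructions", "0:50"),
    (2, "VOD Task Practice", "1:45"),
    (3, "MMN/VOD 1", "5:20"),
    (4, "AOD Task Instruction", "0:38"),
    (5, "AOD Task Practice", "1:45"),
    (6, "AOD 1", "4:15"),
    (7, "MMN/VOD 2", "5:20"),
    (8, "AOD 2", "4:15"),
    (9, "MMN/VOD 3", "5:20"),
    (10, "AOD 3", "4:15"),
    (11, "MMN/VOD 4", "5:20"),
    (12, "AOD 4", "4:15"),
    (13, "MMN/VOD 5", "5:20"),
    (14, "40-Hz ASSR", "2:35"),
    (15, "Resting EEG (eyes open)", "3:05"),
    (16, "Resting EEG (eyes closed)", "3:05"),
)


def _mmss_to_seconds(mmss: str) -> int:
    m, s = mmss.split(":")
    return 60 * int(m) + int(s)


def session_schedule() -> pd.DataFrame:
    """The fixed task run order and per-run durations of one recording session."""
    df = pd.DataFrame(SESSION_SCHEDULE, columns=["order", "task", "duration"])
    df["seconds"] = df["duration"].map(_mmss_to_seconds)
    return df


def total_session_seconds() -> int:
    """Total scheduled recording time of a session, in seconds."""
    return int(session_schedule()["seconds"].sum())
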