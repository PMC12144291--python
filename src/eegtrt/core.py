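"""Core data model: montage, events, raw sessions, and measure tables.

The acquisition setup emulated here is a 64-channel active-electrode cap
(10-10 placement) recorded against an FCz online reference at 1000 Hz, so a
session carries 63 recorded scalp channels plus the implicit FCz reference.
Measures extracted from a session are stored long-format, one row per
(subject, occasion, run, measure), which is the layout the reliability
analyses consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "EventTable",
    "SessionMeta",
    "RawSession",
    "standard_montage",
    "MEASURE_COLUMNS",
    "validate_measure_table",
]

#: Recorded channels of the standard 64-channel actiCAP layout, FCz reference.
#: Order matches the vendor's channel numbering (1-32, 33-63).
ACTICAP64_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2",
)

REFERENCE_LABEL = "FCz"

#: Event vocabulary.
PARADIGMS = ("mmn_vod", "aod", "assr", "rest_open", "rest_closed")
MODALITIES = ("auditory", "visual", "click_train", "response")
CONDITIONS = ("standard", "deviant", "target", "novel", "train", "button")

EVENT_COLUMNS = ["onset", "code", "modality", "condition", "run_index", "paradigm"]

MEASURE_COLUMNS = ["subject_id", "group", "occasion", "run_index", "measure_name", "value"]


@dataclass(frozen=True)
class Montage:
    """Electrode layout: recorded labels, reference label, and unit-sphere positions."""

    channel_labels: tuple[str, ...]
    reference_label: str
    positions: Mapping[str, np.ndarray]

    def __post_init__(self):
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        missing = [c for c in (*self.channel_labels, self.reference_label)
                   if c not in self.positions]
        if missing:
            raise ValueError(f"labels without positions: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def indices(self, labels: Sequence[str]) -> list[int]:
        return [self.index(lb) for lb in labels]

    def position_array(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = self.channel_labels if labels is None else labels
        return np.asarray([self.positions[lb] for lb in labels], dtype=float)

    def with_reference_as_channel(self) -> "Montage":
        """Return a montage whose reference electrode is an explicit recorded channel.

        Used when re-referencing away from the online FCz reference: FCz then
        becomes a scorable data row.
        """
        if self.reference_label in self.channel_labels:
            return self
        return Montage(
            channel_labels=self.channel_labels + (self.reference_label,),
            reference_label=self.reference_label,
            positions=self.positions,
        )


def standard_montage() -> Montage:
    """The fixed 63-channel + FCz-reference 10-10 montage with unit-sphere positions.

    Positions are taken from the standard 10-05 idealized-sphere layout and
    projected onto the unit sphere.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    positions = {}
    for label in (*ACTICAP64_CHANNELS, REFERENCE_LABEL):
        p = np.asarray(pos[label], dtype=float)
        positions[label] = p / np.linalg.norm(p)
    return Montage(ACTICAP64_CHANNELS, REFERENCE_LABEL, positions)


class EventTable:
    """Ordered stimulus/response events of a recording.

    Wraps a DataFrame with columns ``onset`` (s from recording start), ``code``
    (marker code string), ``modality``, ``condition``, ``run_index`` (1-based),
    ``paradigm``. Onsets must be strictly increasing within each paradigm.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, EVENT_COLUMNS].reset_index(drop=True)
        if validate:
            for paradigm, sub in df.groupby("paradigm", sort=False):
                on = sub["onset"].to_numpy(float)
                if np.any(np.diff(on) <= 0):
                    raise ValueError(f"onsets not strictly increasing in {paradigm}")
        self.df = df

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "EventTable":
        return cls(pd.DataFrame.from_records(records, columns=EVENT_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)

    def select(self, *, paradigm=None, condition=None, modality=None,
               run_index=None) -> "EventTable":
        m = pd.Series(True, index=self.df.index)
        if paradigm is not None:
            m &= self.df["paradigm"] == paradigm
        if condition is not None:
            cond = [condition] if isinstance(condition, str) else list(condition)
            m &= self.df["condition"].isin(cond)
        if modality is not None:
            m &= self.df["modality"] == modality
        if run_index is not None:
            m &= self.df["run_index"] == run_index
        return EventTable(self.df.loc[m], validate=False)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset"].to_numpy(float)

    def shifted(self, dt: float) -> "EventTable":
        df = self.df.copy()
        df["onset"] = df["onset"] + dt
        return EventTable(df, validate=False)

    def concat(self, other: "EventTable") -> "EventTable":
        df = pd.concat([self.df, other.df], ignore_index=True)
        df = df.sort_values("onset", kind="stable").reset_index(drop=True)
        return EventTable(df, validate=False)


@dataclass(frozen=True)
class SessionMeta:
    subject_id: str
    group: str = "CON"  # CHR or CON
    occasion: str = "baseline"  # baseline or month2
    inter_session_interval_days: float | None = None

    def __post_init__(self):
        if self.group not in ("CHR", "CON"):
            raise ValueError(f"group must be CHR or CON, got {self.group!r}")
        if self.occasion not in ("baseline", "month2"):
            raise ValueError(f"occasion must be baseline or month2, got {self.occasion!r}")


@dataclass
class RawSession:
    """Continuous multichannel EEG in microvolts plus events and metadata."""

    data: np.ndarray  # channels x samples, microvolts
    sampling_rate: float
    montage: Montage
    events: EventTable
    meta: SessionMeta

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} recorded channels")
        dur = self.duration
        if len(self.events) and np.any(self.events.onsets >= dur):
            raise ValueError("event onset beyond recording duration")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "RawSession":
        return replace(self, data=self.data.copy())

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def with_reference_channel(self) -> "RawSession":
        """Append the online reference (FCz) as an explicit all-zero channel.

        In the FCz-referenced frame the reference electrode is identically
        zero; making it explicit lets FCz-containing clusters be scored after
        re-referencing. No-op if already present.
        """
        mont = self.montage.with_reference_as_channel()
        if mont is self.montage:
            return self
        data = np.vstack([self.data, np.zeros((1, self.n_samples), self.data.dtype)])
        return replace(self, data=data, montage=mont)


def validate_measure_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measure table (one row per subject/occasion/run/measure)."""
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measure table missing columns {missing}")
    df = df.loc[:, MEASURE_COLUMNS]
    keys = ["subject_id", "occasion", "run_index", "measure_name"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate (subject, occasion, run, measure) keys: "
                         f"{df.loc[dup, keys].head().to_dict('records')}")
    return df
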