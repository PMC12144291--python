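"""Readers and writers: BrainVision triplets, the internal archive format, and
measure tables.

BrainVision support covers the multiplexed binary dialect (IEEE float32 for
writing; float32 and 16-bit integer with per-channel resolution for reading).
Stimulus/response markers are mapped to the event vocabulary through a
configurable code map; run boundaries are carried as Comment markers so a
write -> read round trip reproduces the event table exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

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
    validate_measure_table,
)

__all__ = [
    "DEFAULT_CODE_MAP",
    "read_brainvision",
    "write_session",
    "read_archive",
    "write_measures",
    "read_measures",
]

#: marker code -> (paradigm, modality, condition). The stimulus-delivery
#: device's real codes are not public; these defaults are configurable.
DEFAULT_CODE_MAP: dict[str, tuple[str | None, str, str]] = {
    "S  1": ("mmn_vod", "auditory", "standard"),
    "S  2": ("mmn_vod", "auditory", "deviant"),
    "S 11": ("mmn_vod", "visual", "standard"),
    "S 12": ("mmn_vod", "visual", "target"),
    "S 13": ("mmn_vod", "visual", "novel"),
    "S 21": ("aod", "auditory", "standard"),
    "S 22": ("aod", "auditory", "target"),
    "S 23": ("aod", "auditory", "novel"),
    "S 31": ("assr", "click_train", "train"),
    "R  1": (None, "response", "button"),  # paradigm from enclosing run
}

_REVERSE_CODE_MAP = {
    (p, m, c): code for code, (p, m, c) in DEFAULT_CODE_MAP.items() if p is not None
}


def _code_for_event(row) -> str:
    key = (row.paradigm, row.modality, row.condition)
    if row.modality == "response":
        return "R  1"
    if key in _REVERSE_CODE_MAP:
        return _REVERSE_CODE_MAP[key]
    return f"S{int(row.code) if str(row.code).isdigit() else 99:>3d}"


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def _write_brainvision(session: RawSession, header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    eeg_path, vmrk_path = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")
    fs = session.sampling_rate
    n_ch = session.montage.n_channels
    meta = session.meta

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        f"; subject={meta.subject_id} group={meta.group} occasion={meta.occasion}",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lb in enumerate(session.montage.channel_labels, start=1):
        lines.append(f"Ch{i}={lb},{session.montage.reference_label},1,µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    session.data.T.astype("<f4").tofile(eeg_path)

    mk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    k = 2
    last_run: tuple[str, int] | None = None
    for row in session.events.df.itertuples():
        run_key = (row.paradigm, int(row.run_index))
        pos = int(round(row.onset * fs)) + 1  # 1-based sample
        if run_key != last_run:
            mk.append(f"Mk{k}=Comment,run {row.paradigm} {int(row.run_index)},{pos},1,0")
            k += 1
            last_run = run_key
        mtype = "Response" if row.modality == "response" else "Stimulus"
        mk.append(f"Mk{k}={mtype},{_code_for_event(row)},{pos},1,0")
        k += 1
    vmrk_path.write_text("\n".join(mk) + "\n", encoding="utf-8")
    return header_path


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    cur: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            cur = sections.setdefault(line[1:-1], {})
        elif "=" in line:
            key, _, val = line.partition("=")
            cur[key.strip()] = val.strip()
    return sections


def read_brainvision(header_path, code_map=None, montage: Montage | None = None,
                     meta: SessionMeta | None = None) -> RawSession:
    """Read a BrainVision .vhdr/.vmrk/.eeg triplet into a :class:`RawSession`.

    Supports multiplexed IEEE float32 and 16-bit signed integer binaries.
    Markers whose code is absent from ``code_map`` are retained with
    condition ``"unknown"`` and a warning.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    code_map = DEFAULT_CODE_MAP if code_map is None else code_map

    sec = _parse_ini(header_path.read_text(encoding="utf-8", errors="replace"))
    common = sec.get("Common Infos", {})
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    binfmt = sec.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")

    eeg_path = header_path.parent / common["DataFile"]
    vmrk_path = header_path.parent / common["MarkerFile"]
    for p in (eeg_path, vmrk_path):
        if not p.exists():
            raise FileNotFoundError(f"companion file missing: {p}")

    labels, resolutions = [], []
    ch_sec = sec.get("Channel Infos", {})
    for i in range(1, n_ch + 1):
        parts = ch_sec[f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    if binfmt == "IEEE_FLOAT_32":
        flat = np.fromfile(eeg_path, dtype="<f4")
    elif binfmt == "INT_16":
        flat = np.fromfile(eeg_path, dtype="<i2").astype(np.float64)
    else:
        raise ValueError(f"unsupported BinaryFormat {binfmt}")
    data = flat.reshape(-1, n_ch).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    if montage is None:
        std = standard_montage()
        if tuple(labels) == std.channel_labels:
            montage = std
        else:
            # positions for whatever labels the file declares, when standard
            pos = {lb: std.positions[lb] for lb in labels if lb in std.positions}
            ref = common.get("Reference", std.reference_label)
            if len(pos) != len(labels):
                raise ValueError("non-standard channel labels need an explicit montage")
            pos.setdefault(std.reference_label, std.positions[std.reference_label])
            montage = Montage(tuple(labels), ref, pos)

    # markers
    records = []
    run_ctx: dict[str, int] = {}
    cur_paradigm, cur_run = "mmn_vod", 1
    mk_sec = _parse_ini(vmrk_path.read_text(encoding="utf-8", errors="replace"))
    for key in sorted(mk_sec.get("Marker Infos", {}), key=lambda k: int(k[2:])):
        parts = mk_sec["Marker Infos"][key].split(",")
        mtype, desc, pos = parts[0], parts[1], int(parts[2])
        onset = (pos - 1) / fs
        if mtype == "New Segment":
            continue
        if mtype == "Comment":
            if desc.startswith("run "):
                _, cur_paradigm, run_s = desc.split(" ")
                cur_run = int(run_s)
                run_ctx[cur_paradigm] = cur_run
            continue
        if mtype not in ("Stimulus", "Response"):
            continue
        if desc in code_map:
            paradigm, modality, condition = code_map[desc]
            if paradigm is None:
                paradigm = cur_paradigm
        else:
            warnings.warn(f"unmapped marker code {desc!r}; retained as unknown")
            paradigm, modality, condition = cur_paradigm, "response" if mtype == "Response" else "auditory", "unknown"
        records.append(dict(onset=onset, code=desc.strip(), modality=modality,
                            condition=condition, run_index=cur_run, paradigm=paradigm))

    events = (EventTable(pd.DataFrame.from_records(records, columns=EVENT_COLUMNS),
                         validate=False)
              if records else EventTable(pd.DataFrame(columns=EVENT_COLUMNS)))

    if meta is None:
        meta = _meta_from_header(header_path)
    return RawSession(data=data, sampling_rate=fs, montage=montage,
                      events=events, meta=meta)


def _meta_from_header(header_path: Path) -> SessionMeta:
    for line in header_path.read_text(encoding="utf-8", errors="replace").splitlines():
        if line.startswith("; subject="):
            kv = dict(tok.split("=", 1) for tok in line[2:].split())
            return SessionMeta(subject_id=kv.get("subject", "unknown"),
                               group=kv.get("group", "CON"),
                               occasion=kv.get("occasion", "baseline"))
    return SessionMeta(subject_id="unknown")


# ---------------------------------------------------------------------------
# Archive format
# ---------------------------------------------------------------------------

def _write_archive(session: RawSession, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate": session.sampling_rate,
        "channel_labels": list(session.montage.channel_labels),
        "reference_label": session.montage.reference_label,
        "subject_id": session.meta.subject_id,
        "group": session.meta.group,
        "occasion": session.meta.occasion,
        "inter_session_interval_days": session.meta.inter_session_interval_days,
        "n_samples": session.n_samples,
        "dtype": "<f8",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    session.data.astype("<f8").tofile(path / "data.bin")
    session.events.df.to_csv(path / "events.tsv", sep="\t", index=False)
    return path


def read_archive(path, montage: Montage | None = None) -> RawSession:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    data = np.fromfile(path / "data.bin", dtype=meta["dtype"])
    data = data.reshape(len(meta["channel_labels"]), meta["n_samples"])
    if montage is None:
        std = standard_montage()
        pos = {lb: std.positions[lb] for lb in meta["channel_labels"]}
        pos.setdefault(meta["reference_label"], std.positions[meta["reference_label"]])
        montage = Montage(tuple(meta["channel_labels"]), meta["reference_label"], pos)
    edf = pd.read_csv(path / "events.tsv", sep="\t",
                      dtype={"code": str, "condition": str})
    if len(edf) == 0:
        edf = pd.DataFrame(columns=EVENT_COLUMNS)
    events = EventTable(edf, validate=False)
    smeta = SessionMeta(subject_id=str(meta["subject_id"]), group=meta["group"],
                        occasion=meta["occasion"],
                        inter_session_interval_days=meta["inter_session_interval_days"])
    return RawSession(data=data, sampling_rate=meta["sampling_rate"],
                      montage=montage, events=events, meta=smeta)


def write_session(session: RawSession, path, format: str = "archive") -> Path:
    """Write a session to disk as BrainVision or the internal archive format."""
    path = Path(path)
    if format == "brainvision":
        if path.suffix != ".vhdr":
            path = path.with_suffix(".vhdr")
        return _write_brainvision(session, path)
    if format == "archive":
        return _write_archive(session, path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Measure tables
# ---------------------------------------------------------------------------

def write_measures(table: pd.DataFrame, path) -> Path:
    """Write a measure table as TSV with fixed column order."""
    table = validate_measure_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, columns=MEASURE_COLUMNS)
    return path


def read_measures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "run_index": str})
    return validate_measure_table(df)
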