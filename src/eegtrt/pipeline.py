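"""End-to-end orchestration: simulate -> preprocess -> score -> reliability.

A study run synthesizes per-paradigm EEG segments for every person and
occasion, pushes each segment through its preprocessing chain, scores the
ERP/ERO/spectral/behavioral measures into one long measure table, and
estimates per-measure reliability. Everything is deterministic given the
configuration seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as bh
from . import erp as erpmod
from . import preprocess as pp
from . import reliability as rel
from . import sequences as seq
from . import simulate as sim
from . import spectral as sp
from . import timefreq as tf
from .core import MEASURE_COLUMNS, EventTable, RawSession, SessionMeta, standard_montage

__all__ = [
    "PipelineConfig",
    "QCSummary",
    "compact_paradigm_spec",
    "subject_seed",
    "synthesize_study_session",
    "score_session",
    "run_pipeline",
    "EPOCH_WINDOWS",
]

log = logging.getLogger("eegtrt")

#: stimulus-locked epoch windows (s) per paradigm/analysis
EPOCH_WINDOWS = {
    "mmn": (-0.5, 0.5),
    "oddball": (-1.0, 2.0),
    "assr": (-1.248, 1.756),  # analysis output spans -248..752 ms
}


def compact_paradigm_spec(tone_runs: int = 2, tones_per_run: int = 120,
                          vod_per_run: int = 30, aod_runs: int = 2,
                          aod_per_run: int = 40, assr_trains: int = 40,
                          rest_seconds: float = 185.0) -> seq.ParadigmSpec:
    """A shortened paradigm layout with the study's proportions preserved.

    Used for desk-scale end-to-end runs; the full-size default spec remains
    the study condition for sequence-count checks.
    """
    return seq.ParadigmSpec(
        mmn_runs=tone_runs, mmn_tones_per_run=tones_per_run,
        mmn_leading_standards=min(20, tones_per_run // 6),
        vod_runs=tone_runs, vod_stimuli_per_run=vod_per_run,
        aod_runs=aod_runs, aod_stimuli_per_run=aod_per_run,
        assr_trains=assr_trains, rest_seconds=rest_seconds)


@dataclass
class PipelineConfig:
    n_persons: int = 8
    seed: int = 0
    group: str = "CON"
    paradigms: tuple[str, ...] = ("mmn_vod", "aod", "assr", "rest_open",
                                  "rest_closed")
    spec: seq.ParadigmSpec = field(default_factory=compact_paradigm_spec)
    truth: sim.StudyTruth = field(default_factory=sim.default_study_truth)
    clean_artifacts: bool = True
    per_run_scores: bool = True
    rest_epochs: int = 60  # whole-second epochs scored per rest condition

    def to_yaml(self, path) -> None:
        """Archive the full run configuration next to its outputs."""
        import yaml
        doc = dataclasses.asdict(self)
        doc["paradigms"] = list(self.paradigms)
        doc["truth"]["run_decay"] = {k: list(v) for k, v in
                                     self.truth.run_decay.items()}
        doc["truth"]["noise"]["bad_channels"] = list(
            self.truth.noise.bad_channels)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        truth_doc = doc.pop("truth")
        measures = {k: sim.MeasureTruth(**v)
                    for k, v in truth_doc.pop("measures").items()}
        noise_doc = truth_doc.pop("noise")
        noise_doc["bad_channels"] = tuple(noise_doc.get("bad_channels", ()))
        noise = sim.NoiseSpec(**noise_doc)
        behavior = sim.BehaviorSpec(**truth_doc.pop("behavior"))
        run_decay = {k: tuple(v) for k, v in
                     truth_doc.pop("run_decay").items()}
        truth = sim.StudyTruth(measures=measures, run_decay=run_decay,
                               noise=noise, behavior=behavior, **truth_doc)
        spec = seq.ParadigmSpec(**doc.pop("spec"))
        doc["paradigms"] = tuple(doc["paradigms"])
        return cls(spec=spec, truth=truth, **doc)


@dataclass
class QCSummary:
    sessions: list = field(default_factory=list)  # per-session digests

    def add(self, meta: SessionMeta, paradigm: str, report: pp.PreprocReport,
            n_events: int):
        self.sessions.append(dict(
            subject_id=meta.subject_id, occasion=meta.occasion,
            paradigm=paradigm, n_events=n_events,
            bad_channels=list(report.bad_channels),
            n_epochs_rejected=dict(report.n_epochs_rejected),
            n_cca_components_removed=report.n_cca_components_removed,
            low_trial_count=n_events < 20))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sessions)


def subject_seed(base_seed: int, person: int, occasion_index: int,
                 stream: int = 0) -> int:
    """Deterministic per-(person, occasion, stream) seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), person, occasion_index, stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def synthesize_study_session(config: PipelineConfig, person: int,
                             occasion: str,
                             person_effects: dict[str, float],
                             montage=None) -> dict[str, tuple[RawSession, dict]]:
    """All paradigm segments for one person x occasion, with ground truth."""
    montage = montage or standard_montage()
    j = sim.OCCASIONS.index(occasion)
    meta = SessionMeta(subject_id=f"S{person:04d}", group=config.group,
                       occasion=occasion)
    kernels = sim.default_kernels(montage)
    out = {}
    for k, paradigm in enumerate(config.paradigms):
        s = subject_seed(config.seed, person, j, stream=10 + k)
        if paradigm == "mmn_vod":
            ev = seq.generate_mmn_vod_sequence(config.spec, seed=s)
        elif paradigm == "aod":
            ev = seq.generate_aod_sequence(config.spec, seed=s)
        elif paradigm == "assr":
            ev = seq.generate_assr_sequence(config.spec, seed=s)
        else:
            from .core import EVENT_COLUMNS
            ev = EventTable(pd.DataFrame(columns=EVENT_COLUMNS), validate=False)
        dur = None
        if paradigm.startswith("rest"):
            dur = config.spec.rest_seconds
        sess, realized = sim.synthesize_session(
            ev, kernels, config.truth, person_effects, occasion,
            seed=subject_seed(config.seed, person, j, stream=100 + k),
            paradigm=paradigm, duration_s=dur, montage=montage, meta=meta)
        out[paradigm] = (sess, realized)
    return out


def _reref_p7p8(raw: RawSession) -> RawSession:
    """Re-reference to the mean of P7 and P8 (near-mastoid reference used for
    the steady-state analysis), with FCz reconstructed first."""
    sess = raw.with_reference_channel()
    i7 = sess.montage.index("P7")
    i8 = sess.montage.index("P8")
    ref = 0.5 * (sess.data[i7] + sess.data[i8])
    return replace(sess, data=sess.data - ref[None, :])


def score_session(segments: dict[str, RawSession], meta: SessionMeta,
                  *, clean_artifacts: bool = True, per_run: bool = True,
                  rest_epochs: int = 180, qc: QCSummary | None = None
                  ) -> pd.DataFrame:
    """Score one session's paradigm segments into measure-table rows."""
    frames = []
    comp = erpmod.DEFAULT_COMPONENTS

    def add_session_row(name, value):
        frames.append(pd.DataFrame([dict(
            subject_id=meta.subject_id, group=meta.group, occasion=meta.occasion,
            run_index="all", measure_name=name, value=value)],
            columns=MEASURE_COLUMNS))

    if "mmn_vod" in segments:
        raw = segments["mmn_vod"]
        aud = raw.events.select(modality="auditory")
        eps, rep = pp.erp_preprocess(raw, aud, EPOCH_WINDOWS["mmn"],
                                     clean_artifacts=clean_artifacts)
        if qc:
            qc.add(meta, "mmn_vod:aud", rep, len(aud))
        w = erpmod.difference_wave(erpmod.average_erp(eps, "deviant"),
                                   erpmod.average_erp(eps, "standard"))
        add_session_row("mmn", erpmod.score_component(w, comp["mmn"]))
        if per_run:
            frames.append(erpmod.score_by_run(eps, comp["mmn"], meta))

        vis = raw.events.select(modality="visual")
        eps_v, rep_v = pp.erp_preprocess(raw, vis, EPOCH_WINDOWS["oddball"],
                                         clean_artifacts=clean_artifacts)
        if qc:
            qc.add(meta, "mmn_vod:vis", rep_v, len(vis))
        for name in ("vod_p3b", "vod_p3a"):
            w = erpmod.difference_wave(
                erpmod.average_erp(eps_v, comp[name].minuend),
                erpmod.average_erp(eps_v, "standard"))
            add_session_row(name, erpmod.score_component(w, comp[name]))
            if per_run:
                frames.append(erpmod.score_by_run(eps_v, comp[name], meta))
        frames.append(bh.performance_measures(raw.events, "vod", meta))

    if "aod" in segments:
        raw = segments["aod"]
        aud = raw.events.select(modality="auditory")
        eps, rep = pp.erp_preprocess(raw, aud, EPOCH_WINDOWS["oddball"],
                                     clean_artifacts=clean_artifacts)
        if qc:
            qc.add(meta, "aod", rep, len(aud))
        for name in ("aod_p3b", "aod_p3a"):
            w = erpmod.difference_wave(
                erpmod.average_erp(eps, comp[name].minuend),
                erpmod.average_erp(eps, "standard"))
            add_session_row(name, erpmod.score_component(w, comp[name]))
            if per_run:
                frames.append(erpmod.score_by_run(eps, comp[name], meta))
        frames.append(bh.performance_measures(raw.events, "aod", meta))

    if "assr" in segments:
        raw = segments["assr"]
        x = pp.highpass_filter(raw, 0.2)
        x = pp.downsample(x, 250.0)
        x = _reref_p7p8(x)
        eps = pp.epoch(x, x.events.select(condition="train"),
                       EPOCH_WINDOWS["assr"])
        eps = pp.reject_epochs_faster(eps)
        needed = sorted({c for cl in tf.ASSR_CLUSTERS.values() for c in cl})
        tfres = tf.assr_time_frequency(eps, channels=needed)
        frames.append(tf.extract_assr_measures(tfres, meta=meta))

    for paradigm, condition in (("rest_open", "eyes_open"),
                                ("rest_closed", "eyes_closed")):
        if paradigm not in segments:
            continue
        eps, rep = pp.resting_preprocess(segments[paradigm],
                                         n_epochs=rest_epochs)
        if qc:
            qc.add(meta, paradigm, rep, rest_epochs)
        psd = sp.compute_psd(eps, condition=condition)
        frames.append(sp.rest_band_measures(psd, condition, meta))

    return pd.concat(frames, ignore_index=True)[MEASURE_COLUMNS]


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, QCSummary,
                                                  pd.DataFrame]:
    """Full study: synthesize, preprocess, and score every person x occasion,
    then estimate per-measure reliability. Failures are isolated per session."""
    montage = standard_montage()
    effects = sim.draw_person_effects(config.truth, config.n_persons,
                                      seed=subject_seed(config.seed, 0, 0, 1))
    qc = QCSummary()
    frames = []
    for person in range(1, config.n_persons + 1):
        pe = effects.loc[f"S{person:04d}"].to_dict()
        for occasion in sim.OCCASIONS:
            try:
                segs = synthesize_study_session(config, person, occasion, pe,
                                                montage=montage)
                rows = score_session(
                    {k: v[0] for k, v in segs.items()},
                    segs[next(iter(segs))][0].meta,
                    clean_artifacts=config.clean_artifacts,
                    per_run=config.per_run_scores,
                    rest_epochs=config.rest_epochs, qc=qc)
                frames.append(rows)
                log.info("scored %s %s: %d rows", f"S{person:04d}", occasion,
                         len(rows))
            except Exception as exc:  # noqa: BLE001 - isolate failing session
                log.error("session S%04d %s failed: %s", person, occasion, exc)
                qc.sessions.append(dict(subject_id=f"S{person:04d}",
                                        occasion=occasion, paradigm="ALL",
                                        error=str(exc)))
    measures = pd.concat(frames, ignore_index=True)[MEASURE_COLUMNS]
    report = rel.reliability_report(measures, group=config.group)
    return measures, qc, report
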