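import dataclasses

import numpy as np
import pandas as pd
import pytest

from eegtrt import pipeline as pl
from eegtrt import simulate as sim
from eegtrt.core import EVENT_COLUMNS, EventTable, standard_montage


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def kernels(montage):
    return sim.default_kernels(montage)


@pytest.fixture(scope="session")
def silent_truth():
    """Study truth with all noise/artifact sources and habituation disabled
    and zero residual variance: the controlled signal-path condition."""
    truth = sim.default_study_truth()
    return dataclasses.replace(
        truth, noise=truth.noise.silent(), run_decay={}, session_scale={},
        measures={k: dataclasses.replace(v, residual_sd=0.0, occasion_shift=0.0)
                  for k, v in truth.measures.items()})


@pytest.fixture(scope="session")
def zero_effects(silent_truth):
    return {m: 0.0 for m in silent_truth.measures}


@pytest.fixture(scope="session")
def small_spec():
    return pl.compact_paradigm_spec(tone_runs=1, tones_per_run=120,
                                    vod_per_run=30, aod_runs=1, aod_per_run=60,
                                    assr_trains=30, rest_seconds=65.0)


@pytest.fixture
def empty_events():
    return EventTable(pd.DataFrame(columns=EVENT_COLUMNS), validate=False)


def correlated_noise_session(montage, seed, duration_s=20.0, fs=250.0,
                             rms=10.0):
    """A clean, spatially correlated multichannel noise recording."""
    from eegtrt.core import RawSession, SessionMeta
    truth = sim.default_study_truth()
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    bg = sim._one_over_f_noise(rng, montage.n_channels, n, fs, rms,
                               truth.noise.one_over_f_exponent)
    pos = montage.position_array(montage.channel_labels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    M = np.exp(-0.5 * (d / truth.noise.spatial_smoothness) ** 2)
    M /= np.linalg.norm(M, axis=1, keepdims=True)
    ev = EventTable(pd.DataFrame(columns=EVENT_COLUMNS), validate=False)
    return RawSession(data=M @ bg, sampling_rate=fs, montage=montage,
                      events=ev, meta=SessionMeta(subject_id="noise"))
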