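"""Preprocessing stages: filters, bad channels, referencing, epoching,
rejection, artifact separation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import correlated_noise_session
from eegtrt import preprocess as pp
from eegtrt import simulate as sim
from eegtrt.core import EVENT_COLUMNS, EventTable, RawSession, SessionMeta


def _session_from(data, montage, fs=1000.0, events=None):
    ev = events or EventTable(pd.DataFrame(columns=EVENT_COLUMNS), validate=False)
    return RawSession(np.asarray(data, float), fs, montage, ev,
                      SessionMeta("t"))


def _noise63(montage, seed=0, fs=1000.0, dur=4.0):
    rng = np.random.default_rng(seed)
    return _session_from(rng.normal(size=(63, int(fs * dur))), montage, fs)


class TestHighpass:
    def test_dc_rejection(self, montage):
        raw = _session_from(np.full((63, 4000), 50.0), montage)
        out = pp.highpass_filter(raw, 0.2)
        assert np.abs(out.data[:, 500:-500]).mean() < 1e-3 * 50.0

    def test_passband_gain(self, montage):
        fs, dur = 1000.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        raw = _session_from(np.tile(np.sin(2 * np.pi * 10 * t), (63, 1)),
                            montage, fs)
        out = pp.highpass_filter(raw, 0.2)
        mid = out.data[0, 2000:-2000]
        amp = (mid.max() - mid.min()) / 2
        assert abs(amp - 1.0) < 0.01

    def test_cutoff_above_nyquist(self, montage):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.highpass_filter(_noise63(montage), 500.0)


class TestDownsample:
    def test_sample_count_quartered(self, montage):
        out = pp.downsample(_noise63(montage, dur=4.0), 250.0)
        assert out.n_samples == 1000 and out.sampling_rate == 250.0

    def test_antialias_contract(self, montage):
        fs = 1000.0
        t = np.arange(int(fs * 20)) / fs
        sig = np.sin(2 * np.pi * 30 * t)
        hf = np.sin(2 * np.pi * 200 * t)
        raw = _session_from(np.vstack([np.tile(sig, (32, 1)),
                                       np.tile(hf, (31, 1))]), montage, fs)
        out = pp.downsample(raw, 250.0)
        lo = out.data[0, 500:-500]
        amp_lo = (lo.max() - lo.min()) / 2
        assert abs(amp_lo - 1.0) < 0.02
        rms_hf = out.data[-1, 500:-500].std()
        assert 20 * np.log10(rms_hf / (1 / np.sqrt(2))) < -40.0

    def test_event_times_preserved(self, montage):
        ev = EventTable.from_records([dict(
            onset=1.0, code="1", modality="auditory", condition="standard",
            run_index=1, paradigm="mmn_vod")])
        raw = _session_from(np.zeros((63, 4000)), montage, events=ev)
        out = pp.downsample(raw, 250.0)
        assert out.events.onsets[0] == 1.0

    def test_non_divisor_target(self, montage):
        with pytest.raises(ValueError, match="divide"):
            pp.downsample(_noise63(montage), 300.0)


class TestBadChannels:
    def test_huge_noise_channel_flagged(self, montage):
        raw = correlated_noise_session(montage, seed=1)
        i = raw.montage.index("C3")
        rng = np.random.default_rng(0)
        raw.data[i] = 100.0 * raw.data.std() * rng.normal(size=raw.n_samples)
        assert "C3" in pp.detect_bad_channels(raw)

    def test_flat_channel_flagged_by_correlation(self, montage):
        raw = correlated_noise_session(montage, seed=2)
        raw.data[raw.montage.index("P3")] = 0.0
        assert "P3" in pp.detect_bad_channels(raw)

    def test_specificity_on_clean_data(self, montage):
        false_flags = 0
        for s in range(50):
            raw = correlated_noise_session(montage, seed=100 + s,
                                           duration_s=8.0)
            false_flags += len(pp.detect_bad_channels(raw))
        assert false_flags <= 50  # on average <= 1 spurious flag per record

    def test_too_few_channels(self, montage):
        from eegtrt.core import Montage
        labels = montage.channel_labels[:4]
        m = Montage(labels, "FCz", montage.positions)
        raw = RawSession(np.random.default_rng(0).normal(size=(4, 1000)),
                         250.0, m,
                         EventTable(pd.DataFrame(columns=EVENT_COLUMNS),
                                    validate=False), SessionMeta("t"))
        with pytest.raises(ValueError, match="8 channels"):
            pp.detect_bad_channels(raw)


class TestInterpolation:
    def test_plant_and_recover_smooth_field(self, montage):
        # smooth spatial field = dipole-like pattern from a few broad sources
        rng = np.random.default_rng(3)
        pos = montage.position_array(montage.channel_labels)
        t = np.arange(2500) / 250.0
        sources = [(pos @ montage.positions[lb]) ** 3 for lb in
                   ("Cz", "POz", "F3")]
        data = sum(np.outer(s, np.sin(2 * np.pi * f * t + ph)) for s, f, ph in
                   zip(sources, (5.0, 9.0, 3.0), (0.0, 1.0, 2.0)))
        raw = _session_from(data, montage, fs=250.0)
        truth = raw.data[montage.index("C1")].copy()
        corrupted = raw.copy()
        corrupted.data[montage.index("C1")] = rng.normal(size=raw.n_samples)
        out = pp.interpolate_channels(corrupted, ["C1"])
        r = np.corrcoef(out.data[montage.index("C1")], truth)[0, 1]
        assert r > 0.9

    def test_empty_list_is_identity(self, montage):
        raw = _noise63(montage)
        out = pp.interpolate_channels(raw, [])
        np.testing.assert_array_equal(out.data, raw.data)

    def test_unknown_label(self, montage):
        with pytest.raises(ValueError, match="not in montage"):
            pp.interpolate_channels(_noise63(montage), ["XX"])


class TestRobustReference:
    def test_included_mean_zero(self, montage):
        raw = correlated_noise_session(montage, seed=4)
        out = pp.robust_average_reference(raw)
        labels = out.montage.channel_labels
        inc = [i for i, lb in enumerate(labels)
               if lb not in pp.REFERENCE_EXCLUDE]
        assert np.abs(out.data[inc].mean(axis=0)).max() < 1e-9

    def test_robust_against_one_huge_channel(self, montage):
        raw = correlated_noise_session(montage, seed=5)
        clean_ref = raw.data[[i for i, lb in
                              enumerate(montage.channel_labels)
                              if lb not in pp.REFERENCE_EXCLUDE]].mean(axis=0)
        i = montage.index("C3")
        rng = np.random.default_rng(0)
        raw.data[i] += 200.0 * rng.normal(size=raw.n_samples)
        naive_ref = raw.data[[i for i, lb in
                              enumerate(montage.channel_labels)
                              if lb not in pp.REFERENCE_EXCLUDE]].mean(axis=0)
        # recompute what reference the robust procedure effectively used
        out = pp.robust_average_reference(raw, interpolate_bads=False)
        used_ref = raw.data[montage.index("Oz")] - out.data[
            out.montage.index("Oz")]
        rms = lambda x: np.sqrt(np.mean(x ** 2))  # noqa: E731
        assert rms(used_ref - clean_ref) < 0.05 * rms(clean_ref) + 0.5
        assert rms(naive_ref - clean_ref) > rms(used_ref - clean_ref)

    def test_excluded_channel_shape_preserved(self, montage):
        raw = correlated_noise_session(montage, seed=6)
        blink = np.zeros(raw.n_samples)
        blink[1000:1100] = 80.0
        raw.data[montage.index("Fp1")] += blink
        out = pp.robust_average_reference(raw)
        ref = raw.data[montage.index("Oz")] - out.data[out.montage.index("Oz")]
        recovered = out.data[out.montage.index("Fp1")] + ref
        np.testing.assert_allclose(recovered, raw.data[montage.index("Fp1")],
                                   atol=1e-9)


class TestEpoching:
    def _raw_with_events(self, montage, onsets, fs=250.0, dur=10.0):
        ev = EventTable.from_records([dict(
            onset=o, code="1", modality="auditory", condition="standard",
            run_index=1, paradigm="mmn_vod") for o in onsets])
        rng = np.random.default_rng(0)
        return _session_from(rng.normal(size=(63, int(fs * dur))), montage,
                             fs, events=ev)

    def test_mmn_window_sample_count(self, montage):
        raw = self._raw_with_events(montage, [2.0, 4.0, 6.0])
        eps = pp.epoch(raw, raw.events, (-0.5, 0.5))
        assert eps.data.shape == (3, 63, 250)
        assert eps.times[0] == -0.5 and eps.times[-1] < 0.5

    def test_edge_event_dropped(self, montage):
        raw = self._raw_with_events(montage, [0.1, 5.0])
        with pytest.warns(UserWarning, match="edges"):
            eps = pp.epoch(raw, raw.events, (-0.5, 0.5))
        assert eps.n_epochs == 1

    def test_window_must_bracket_zero(self, montage):
        raw = self._raw_with_events(montage, [5.0])
        with pytest.raises(ValueError, match="bracket"):
            pp.epoch(raw, raw.events, (0.5, 1.0))

    def test_empty_selection(self, montage):
        raw = self._raw_with_events(montage, [5.0])
        with pytest.raises(ValueError, match="empty"):
            pp.epoch(raw, raw.events.select(condition="deviant"), (-0.5, 0.5))


def _epochs_from_array(data, fs=250.0, t0=-0.1):
    n_ep, n_ch, n_t = data.shape
    return pp.EpochSet(
        data=np.asarray(data, float),
        times=t0 + np.arange(n_t) / fs, sampling_rate=fs,
        channel_labels=tuple(f"ch{i}" for i in range(n_ch)),
        conditions=np.array(["standard"] * n_ep, object),
        run_indices=np.ones(n_ep, int), rejected=np.zeros(n_ep, bool),
        reject_reason=[None] * n_ep)


class TestFasterRejection:
    def test_planted_outlier_uniquely_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(51, 8, 100))
        data[17] *= 10.0
        out = pp.reject_epochs_faster(_epochs_from_array(data))
        assert out.rejected[17]
        assert out.rejected.sum() == 1

    def test_identical_epochs_none_rejected(self):
        data = np.tile(np.random.default_rng(1).normal(size=(1, 8, 100)),
                       (20, 1, 1))
        out = pp.reject_epochs_faster(_epochs_from_array(data))
        assert out.rejected.sum() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_zscore_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(30, 5, 80)) * rng.uniform(0.5, 2.0,
                                                          size=(30, 1, 1))
        out = pp.reject_epochs_faster(_epochs_from_array(data))
        # independent oracle: explicit loops over the three statistics
        stats = np.array([
            [d.mean(), d.var(axis=1).mean(), np.ptp(d, axis=1).mean()]
            for d in data])
        expect = np.zeros(30, bool)
        for j in range(3):
            col = stats[:, j]
            z = (col - col.mean()) / col.std()
            expect |= np.abs(z) >= 3
        np.testing.assert_array_equal(out.rejected, expect)

    def test_needs_three_epochs(self):
        with pytest.raises(ValueError):
            pp.reject_epochs_faster(_epochs_from_array(np.zeros((2, 4, 50))))


class TestBssCca:
    def _erp_epochs(self, seed=0, n_ep=40, n_ch=12, n_t=250):
        rng = np.random.default_rng(seed)
        t = np.arange(n_t) / 250.0
        base = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 9 * t)
        mix = rng.uniform(0.5, 1.5, size=(n_ch, 3))
        slow = np.stack([np.sin(2 * np.pi * f * t + p) for f, p in
                         zip((4, 7, 11), (0, 1, 2))])
        data = np.tile(mix @ slow + base, (n_ep, 1, 1))
        # low-passed jitter keeps the data full-rank yet purely low-frequency
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, 20.0, btype="lowpass", fs=250.0, output="sos")
        data += sosfiltfilt(sos, 0.05 * rng.normal(size=data.shape), axis=2)
        return _epochs_from_array(data)

    def test_specificity_on_low_frequency_data(self):
        eps = self._erp_epochs()
        out, rep = pp.bsscca_muscle_removal(eps)
        assert rep.n_cca_components_removed == 0
        err = np.sqrt(np.mean((out.data - eps.data) ** 2))
        assert err < 1e-6

    def test_plant_and_remove_burst(self):
        from scipy.signal import butter, sosfiltfilt, welch
        eps = self._erp_epochs(seed=1)
        rng = np.random.default_rng(2)
        sos = butter(4, [60, 90], btype="bandpass", fs=250.0, output="sos")
        dirty = eps.copy()
        for e in range(0, dirty.n_epochs, 2):
            burst = sosfiltfilt(sos, rng.normal(size=dirty.data.shape[2] + 100))
            burst = 5.0 * burst[50:-50] / burst.std()
            for ch in (3, 4, 5):
                dirty.data[e, ch] += burst * (1 - 0.2 * (ch - 3))
        out, rep = pp.bsscca_muscle_removal(dirty)
        assert rep.n_cca_components_removed >= 1

        def band_power(x, lo, hi):
            f, p = welch(x.reshape(-1, x.shape[-1]), fs=250.0, nperseg=128,
                         axis=1)
            return p[:, (f >= lo) & (f <= hi)].sum()

        burst_before = band_power(dirty.data[:, 3:6], 60, 90)
        burst_after = band_power(out.data[:, 3:6], 60, 90)
        assert burst_after < 0.2 * burst_before
        erp_before = dirty.data[1::2, :, :]  # clean epochs, 1-15 Hz content
        erp_after = out.data[1::2, :, :]
        dist = np.sqrt(np.mean((erp_after - erp_before) ** 2))
        assert dist < 0.05 * np.sqrt(np.mean(erp_before ** 2))

    def test_component_order_monotone_in_autocorrelation(self):
        eps = self._erp_epochs(seed=3)
        _, rep = pp.bsscca_muscle_removal(eps)
        rho = np.array(rep.notes[0]["cca_autocorr"])
        assert np.all(np.diff(rho) <= 1e-9)


class TestOcular:
    def _blinky_epochs(self, montage, blink_gain=1.0, seed=0, n_ep=30):
        rng = np.random.default_rng(seed)
        n_ch = 63
        n_t = 250
        labels = montage.channel_labels
        data = rng.normal(size=(n_ep, n_ch, n_t))
        pos = montage.position_array(labels)
        fp_mid = 0.5 * (montage.positions["Fp1"] + montage.positions["Fp2"])
        topo = np.exp(-0.5 * (np.linalg.norm(pos - fp_mid, axis=1) / 0.35) ** 2)
        blink = np.sin(np.pi * np.arange(100) / 100) ** 2
        for e in range(0, n_ep, 3):
            i0 = rng.integers(20, 120)
            data[e, :, i0:i0 + 100] += blink_gain * 60.0 * np.outer(topo, blink)
        eps = _epochs_from_array(data)
        eps.channel_labels = labels
        return eps

    def test_blink_power_reduced_frontally(self, montage):
        from scipy.signal import butter, sosfiltfilt
        eps = self._blinky_epochs(montage)
        out, rep = pp.remove_ocular(eps)
        assert rep.n_ocular_components_removed == 1
        sos = butter(4, (0.5, 8.0), btype="bandpass", fs=250.0, output="sos")
        ifz = eps.channel_labels.index("Fz")

        def blink_band_power(x):
            return np.mean(sosfiltfilt(sos, x[:, ifz, :].reshape(-1)) ** 2)

        assert blink_band_power(out.data) < 0.3 * blink_band_power(eps.data)

    def test_blink_free_data_untouched(self, montage):
        eps = self._blinky_epochs(montage, blink_gain=0.0)
        out, rep = pp.remove_ocular(eps)
        change = np.sqrt(np.mean((out.data - eps.data) ** 2))
        assert change < 0.02 * np.sqrt(np.mean(eps.data ** 2))

    def test_occipital_nearly_unchanged(self, montage):
        eps = self._blinky_epochs(montage)
        out, _ = pp.remove_ocular(eps)
        ioz = eps.channel_labels.index("Oz")
        change = np.sqrt(np.mean((out.data[:, ioz] - eps.data[:, ioz]) ** 2))
        assert change < 0.05 * np.sqrt(np.mean(eps.data[:, ioz] ** 2))

    def test_missing_proxy_channels(self):
        eps = _epochs_from_array(np.zeros((5, 4, 100)))
        with pytest.raises(ValueError, match="proxy"):
            pp.remove_ocular(eps)


class TestBaseline:
    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(0)
        eps = _epochs_from_array(rng.normal(size=(10, 6, 250)))
        out = pp.baseline_correct(eps, (-0.1, 0.0))
        mask = (out.times >= -0.1) & (out.times < 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-9

    def test_constant_epoch_zeroed(self):
        eps = _epochs_from_array(np.full((5, 3, 250), 7.0))
        out = pp.baseline_correct(eps)
        assert np.abs(out.data).max() < 1e-12

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        eps = _epochs_from_array(rng.normal(size=(5, 3, 250)))
        shifted = eps.copy()
        shifted.data += 42.0
        np.testing.assert_allclose(pp.baseline_correct(eps).data,
                                   pp.baseline_correct(shifted).data,
                                   atol=1e-10)

    def test_window_outside_epoch(self):
        eps = _epochs_from_array(np.zeros((5, 3, 250)))
        with pytest.raises(ValueError):
            pp.baseline_correct(eps, (-5.0, -4.0))


@pytest.fixture(scope="module")
def rest_raw(montage):
    truth = sim.default_study_truth()
    noise = dataclasses.replace(truth.noise, bad_channels=("P3",))
    truth = dataclasses.replace(truth, noise=noise)
    ev = EventTable(pd.DataFrame(columns=EVENT_COLUMNS), validate=False)
    sess, _ = sim.synthesize_session(
        ev, {}, truth, {}, seed=8, paradigm="rest_open",
        duration_s=185.0, montage=montage)
    return sess


class TestRestingChain:

    def test_full_rest_run_yields_180_epochs(self, rest_raw):
        eps, rep = pp.resting_preprocess(rest_raw, n_epochs=180)
        assert eps.n_epochs == 180

    def test_common_average_holds(self, rest_raw):
        eps, _ = pp.resting_preprocess(rest_raw, n_epochs=180)
        assert np.abs(eps.data.mean(axis=1)).max() < 1e-9

    def test_planted_bad_channel_detected(self, rest_raw):
        _, rep = pp.resting_preprocess(rest_raw, n_epochs=180)
        assert "P3" in rep.bad_channels

    def test_short_run_rejected(self, montage):
        short = correlated_noise_session(montage, seed=9, duration_s=30.0)
        with pytest.raises(ValueError, match="shorter"):
            pp.resting_preprocess(short, n_epochs=180)
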