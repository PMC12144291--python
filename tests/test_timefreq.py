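"""Morlet wavelet decomposition, ITC, and power measures."""

import numpy as np
import pytest

from eegtrt import preprocess as pp
from eegtrt import timefreq as tf


class TestWaveletSpec:
    def test_constant_schedule(self):
        assert tf.wavelet_spec(40.0).constant == 14.0
        assert tf.wavelet_spec(20.0).constant == 7.0
        assert tf.wavelet_spec(30.0).constant == 10.5
        assert tf.wavelet_spec(4.0).constant == 7.0
        assert tf.wavelet_spec(100.0).constant == 14.0

    def test_printed_bandwidth_at_40hz(self):
        spec = tf.wavelet_spec(40.0)
        assert abs(6 * spec.sigma_f - 17.1429) < 1e-3

    def test_equal_bandwidth_across_transition(self):
        for f in np.arange(20.0, 40.0 + 1e-9, 0.5):
            assert abs(6 * tf.wavelet_spec(f).sigma_f - 120.0 / 7.0) < 1e-9

    def test_sigma_relationship(self):
        spec = tf.wavelet_spec(30.0)
        assert abs(spec.sigma_f - 30.0 / 10.5) < 1e-12
        assert abs(spec.sigma_t - 1 / (2 * np.pi * spec.sigma_f)) < 1e-15
        assert spec.duration == 6 * spec.sigma_t

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            tf.wavelet_spec(0.0)


def _sine_epochs(freq, n_tr=5, fs=250.0, dur=3.0, amp=1.0, phases=None):
    t = np.arange(int(fs * dur)) / fs - 1.25
    if phases is None:
        phases = np.zeros(n_tr)
    data = np.stack([amp * np.sin(2 * np.pi * freq * t + ph)
                     for ph in phases])[:, None, :]
    return data, t


class TestMorletTransform:
    def test_unit_sinusoid_amplitude_and_peak_bin(self):
        data, t = _sine_epochs(40.0, n_tr=1)
        c, times = tf.morlet_transform(data, t, 250.0,
                                       freqs=tf.ASSR_FREQS,
                                       output_window_s=(-0.2, 0.7))
        mag = np.abs(c[0, 0])
        peak_bin = tf.ASSR_FREQS[np.argmax(mag.mean(axis=1))]
        assert peak_bin == 40.0
        mid = mag[np.argmax(mag.mean(axis=1))]
        assert np.allclose(mid, 1.0, rtol=0.02)

    def test_linearity(self):
        data, t = _sine_epochs(40.0, n_tr=1)
        c1, _ = tf.morlet_transform(data, t, 250.0, freqs=[40.0],
                                    output_window_s=(-0.2, 0.7))
        c2, _ = tf.morlet_transform(2 * data, t, 250.0, freqs=[40.0],
                                    output_window_s=(-0.2, 0.7))
        np.testing.assert_allclose(np.abs(c2), 2 * np.abs(c1), rtol=1e-9)

    def test_frequency_separation(self):
        d30, t = _sine_epochs(30.0, n_tr=1)
        d80, _ = _sine_epochs(80.0, n_tr=1)
        c, _ = tf.morlet_transform(d30 + d80, t, 250.0,
                                   freqs=[30.0, 54.0, 80.0],
                                   output_window_s=(-0.2, 0.7))
        mag = np.abs(c[0, 0]).mean(axis=1)
        assert mag[1] < 0.1 * mag[0] and mag[1] < 0.1 * mag[2]

    def test_too_short_epoch(self):
        t = np.arange(100) / 250.0 - 0.2  # 0.4 s epoch centered on 0
        data = np.sin(2 * np.pi * 4.0 * t)[None, None, :]
        with pytest.raises(ValueError, match="too short"):
            tf.morlet_transform(data, t, 250.0, freqs=[4.0],
                                output_window_s=(-0.1, 0.1))


class TestItc:
    def _coeffs(self, phases):
        c = np.exp(1j * np.asarray(phases))[:, None, None, None]
        return np.tile(c, (1, 1, 1, 5))

    def test_identical_phases(self):
        r = tf.itc(self._coeffs([0.3] * 8), np.arange(5) / 250.0, [40.0],
                   ("FCz",))
        np.testing.assert_allclose(r.values, 1.0)

    def test_symmetric_cancellation(self):
        r = tf.itc(self._coeffs([0, np.pi / 2, np.pi, 3 * np.pi / 2]),
                   np.arange(5) / 250.0, [40.0], ("FCz",))
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_uniform_phase_expectation(self):
        """Mean resultant length of n uniform phases ~ sqrt(pi)/(2 sqrt(n))."""
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            ph = rng.uniform(0, 2 * np.pi, size=100)
            vals.append(float(np.abs(np.exp(1j * ph).mean())))
        expect = np.sqrt(np.pi) / (2 * np.sqrt(100))
        assert abs(np.mean(vals) - expect) < 0.01
        # and the package path agrees (200 independent time points)
        c = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(100, 1, 1, 200)))
        r = tf.itc(c, np.arange(200) / 250.0, [40.0], ("FCz",))
        assert abs(r.values.mean() - expect) < 0.01

    def test_amplitude_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(0, 2 * np.pi, size=(20, 1, 1, 10))
        amp = rng.uniform(0.1, 5.0, size=ph.shape)
        r1 = tf.itc(np.exp(1j * ph), np.arange(10) / 250.0, [40.0], ("a",))
        r2 = tf.itc(amp * np.exp(1j * ph), np.arange(10) / 250.0, [40.0],
                    ("a",))
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)
        assert np.all((r1.values >= 0) & (r1.values <= 1))

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            tf.itc(np.ones((1, 1, 1, 5), complex), np.arange(5) / 250.0,
                   [40.0], ("a",))


def _stationary_coeffs(rng, n_tr=30, n_t=300, amp_post=1.0):
    """Coefficients with baseline amplitude 1 and post-stimulus ``amp_post``;
    time axis includes the -200..-100 ms baseline."""
    times = (np.arange(n_t) - 100) / 250.0  # -0.4 .. 0.796 s
    amp = np.where(times < 0, 1.0, amp_post)
    ph = rng.uniform(0, 2 * np.pi, size=(n_tr, 1, 1, n_t))
    return amp[None, None, None, :] * np.exp(1j * ph), times


class TestPower:
    def test_stationary_signal_near_zero_db(self):
        c, times = _stationary_coeffs(np.random.default_rng(0))
        r = tf.total_power(c, times, [40.0], ("a",))
        assert np.abs(r.values).max() < 0.5

    def test_amplitude_doubling_gives_6db(self):
        c, times = _stationary_coeffs(np.random.default_rng(1), amp_post=2.0)
        r = tf.total_power(c, times, [40.0], ("a",))
        post = r.values[0, 0, times >= 0.1]
        assert abs(post.mean() - 6.02) < 0.1

    def test_total_power_phase_invariant(self):
        rng = np.random.default_rng(2)
        c, times = _stationary_coeffs(rng)
        shuffled = np.abs(c) * np.exp(1j * rng.uniform(0, 2 * np.pi, c.shape))
        r1 = tf.total_power(c, times, [40.0], ("a",))
        r2 = tf.total_power(shuffled, times, [40.0], ("a",))
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-9)


class TestEvokedPower:
    def test_phase_locked_identity(self):
        """For perfectly locked trials, evoked power equals the linear-domain
        post-stimulus increase of total power."""
        rng = np.random.default_rng(3)
        times = (np.arange(300) - 100) / 250.0
        amp = np.where(times < 0, 0.5, 1.5)
        c = np.tile(amp[None, None, None, :] * np.exp(1j * 0.7), (20, 1, 1, 1))
        ev = tf.evoked_power(c.mean(axis=0), times, [40.0], ("a",))
        total_lin = np.mean(np.abs(c) ** 2, axis=0)
        total_lin -= total_lin[..., (times >= -0.2) & (times <= -0.1)].mean()
        np.testing.assert_allclose(ev.values, total_lin, atol=1e-9)

    def test_random_phases_cancel(self):
        rng = np.random.default_rng(4)
        ph = rng.uniform(0, 2 * np.pi, size=(2000, 1, 1, 50))
        c = np.exp(1j * ph)
        ev = tf.evoked_power(c.mean(axis=0), (np.arange(50) - 45) / 250.0,
                             [40.0], ("a",))
        tot = np.mean(np.abs(c) ** 2)
        assert np.abs(ev.values).max() < 0.05 * tot

    def test_zero_input(self):
        c = np.zeros((1, 1, 300), complex)
        times = (np.arange(300) - 100) / 250.0
        ev = tf.evoked_power(c, times, [40.0], ("a",))
        np.testing.assert_allclose(ev.values, 0.0)


class TestAssrExtraction:
    def _tfres(self, values, freqs, labels=("FCz", "FC1", "FC2", "Cz", "C1",
                                            "C2", "Fz", "F1", "F2")):
        times = np.arange(-0.248, 0.7521, 0.004)
        vals = np.broadcast_to(values, (len(labels), len(freqs),
                                        len(times))).copy()
        return tf.TFResult("itc", vals, np.asarray(freqs, float), times,
                           labels, 10)

    def test_uses_only_the_three_center_bins(self):
        freqs = np.arange(4.0, 101.0, 2.0)
        base = np.zeros((len(freqs), 1))
        for f in (38.0, 40.0, 42.0):
            base[freqs == f] = 0.6
        r = self._tfres(base[None, :, :], freqs)
        out = {"assr_itc": r}
        v1 = tf.extract_assr_measures(out).value.iloc[0]
        r.values[:, freqs == 44.0, :] = 99.0  # outside the 4-Hz bin
        v2 = tf.extract_assr_measures({"assr_itc": r}).value.iloc[0]
        assert v1 == pytest.approx(0.6)
        assert v2 == v1

    def test_missing_cluster_channel(self):
        r = self._tfres(np.zeros((1, 49, 1)), np.arange(4.0, 101.0, 2.0),
                        labels=("FCz",))
        with pytest.raises(ValueError, match="missing"):
            tf.extract_assr_measures({"assr_itc": r})


class TestTFResultIO:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        r = tf.TFResult("itc", rng.uniform(size=(2, 3, 5)),
                        np.array([38.0, 40.0, 42.0]),
                        np.arange(5) / 250.0, ("FCz", "Cz"), 12)
        r.save(tmp_path / "itc")
        back = tf.TFResult.load(tmp_path / "itc")
        np.testing.assert_array_equal(back.values, r.values)
        assert back.kind == "itc" and back.channel_labels == ("FCz", "Cz")
        assert back.n_trials == 12


class TestOracleAndMonotonicity:
    def test_hilbert_bandpass_oracle_agreement(self):
        """Wavelet ITC/power at one frequency agrees with an independent
        FFT-bandpass + Hilbert-phase implementation."""
        from scipy.signal import butter, hilbert, sosfiltfilt
        rng = np.random.default_rng(5)
        fs, n_tr = 250.0, 60
        t = np.arange(int(fs * 3)) / fs - 1.25
        kappa = 3.0
        phases = rng.vonmises(0.0, kappa, size=n_tr)
        data = np.stack([np.sin(2 * np.pi * 40.0 * t + ph)
                         + 0.3 * rng.normal(size=t.size) for ph in phases])
        data = data[:, None, :]
        c, times = tf.morlet_transform(data, t, fs, freqs=[40.0],
                                       output_window_s=(0.1, 0.5))
        itc_w = tf.itc(c, times, [40.0], ("a",)).values.mean()
        # oracle
        sos = butter(4, [36.0, 44.0], btype="bandpass", fs=fs, output="sos")
        analytic = hilbert(sosfiltfilt(sos, data[:, 0, :], axis=1), axis=1)
        sel = (t >= 0.1) & (t <= 0.5)
        ph = analytic[:, sel] / np.abs(analytic[:, sel])
        itc_h = np.abs(ph.mean(axis=0)).mean()
        assert abs(itc_w - itc_h) < 0.02 * max(itc_w, itc_h) + 0.01

    def test_itc_monotone_in_concentration(self):
        rng = np.random.default_rng(6)
        fs = 250.0
        t = np.arange(int(fs * 3)) / fs - 1.25
        vals = []
        for kappa in (0.0, 1.0, 4.0, 16.0, np.inf):
            phases = (np.zeros(100) if np.isinf(kappa)
                      else rng.vonmises(0.0, max(kappa, 1e-9), size=100))
            data = np.stack([np.sin(2 * np.pi * 40.0 * t + ph)
                             for ph in phases])[:, None, :]
            c, times = tf.morlet_transform(data, t, fs, freqs=[40.0],
                                           output_window_s=(0.1, 0.5))
            vals.append(tf.itc(c, times, [40.0], ("a",)).values.mean())
        assert np.all(np.diff(vals) > -0.02)
        assert vals[-1] > 0.999


class TestEndToEndAssr:
    def test_perfect_locking_gives_unit_itc(self, montage, silent_truth,
                                            zero_effects, kernels, small_spec):
        import dataclasses

        from eegtrt import sequences as seq
        from eegtrt.pipeline import EPOCH_WINDOWS, _reref_p7p8
        truth = dataclasses.replace(silent_truth,
                                    assr_phase_jitter_kappa=np.inf)
        from eegtrt import simulate as sim
        ev = seq.generate_assr_sequence(small_spec, seed=1)
        sess, _ = sim.synthesize_session(ev, {"assr": kernels["assr"]}, truth,
                                         zero_effects, seed=2, montage=montage)
        x = pp.downsample(pp.highpass_filter(sess, 0.2), 250.0)
        x = _reref_p7p8(x)
        eps = pp.epoch(x, x.events.select(condition="train"),
                       EPOCH_WINDOWS["assr"])
        res = tf.assr_time_frequency(eps, channels=["FCz", "FC1", "FC2",
                                                    "Cz", "C1", "C2", "Fz",
                                                    "F1", "F2"])
        out = tf.extract_assr_measures(res)
        itc_val = out.loc[out.measure_name == "assr_itc", "value"].iloc[0]
        assert abs(itc_val - 1.0) < 1e-3
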