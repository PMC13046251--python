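"""Preprocessing tests: resampling, zero-phase bandpass, the five ICA
artifact criteria, and interictal z-scoring."""

import numpy as np
import pytest
from scipy import signal as sps

from chimerapred.core import MultiChannelSignal
from chimerapred.preprocess import (bandpass, flag_artifact_components,
                                    preprocess_pipeline, resample_to,
                                    zscore_interictal)


def make_signal(data, rate, names=None):
    return MultiChannelSignal(data=np.atleast_2d(data), sampling_rate=rate,
                              channel_names=names or [])


class TestResample:
    def test_exact_two_to_one_decimation_length(self):
        sig = make_signal(np.random.default_rng(0).normal(size=(2, 1024)), 512.0)
        out = resample_to(sig, 256.0)
        assert out.n_samples == 512 and out.sampling_rate == 256.0

    def test_pure_tone_matches_analytic_waveform(self):
        t = np.arange(4096) / 512.0
        sig = make_signal(np.sin(2 * np.pi * 10 * t), 512.0)
        out = resample_to(sig, 256.0)
        ref = np.sin(2 * np.pi * 10 * np.arange(out.n_samples) / 256.0)
        r = np.corrcoef(out.data[0][50:-50], ref[50:-50])[0, 1]
        assert r > 0.999

    def test_identity_rate_returns_equal_signal(self):
        sig = make_signal(np.random.default_rng(1).normal(size=(3, 256)), 256.0)
        out = resample_to(sig, 256.0)
        assert np.array_equal(out.data, sig.data)


class TestBandpass:
    def test_dc_offset_removed(self):
        t = np.arange(2048) / 256.0
        sig = make_signal(5.0 + np.sin(2 * np.pi * 10 * t), 256.0)
        out = bandpass(sig)
        assert abs(out.data.mean()) < 1e-2

    def test_60hz_attenuation_matches_squared_response_oracle(self):
        """Forward-backward filtering attenuates a 60 Hz tone by the squared
        Butterworth magnitude response (~19 dB at these corners)."""
        t = np.arange(4096) / 256.0
        x = np.sin(2 * np.pi * 60 * t)
        out = bandpass(make_signal(x, 256.0))
        core = slice(256, -256)
        atten_db = 20 * np.log10(np.std(x[core]) / np.std(out.data[0][core]))
        sos = sps.butter(4, [1.0, 50.0], btype="bandpass", fs=256.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[60.0], fs=256.0)
        oracle_db = -40.0 * np.log10(abs(h[0]))  # doubled by the two passes
        assert atten_db == pytest.approx(oracle_db, abs=1.0)
        assert atten_db > 15.0

    def test_passband_gain_and_zero_phase(self):
        t = np.arange(4096) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(make_signal(x, 256.0))
        core = slice(256, -256)
        gain = np.std(out.data[0][core]) / np.std(x[core])
        assert 0.95 < gain < 1.05
        xc = sps.correlate(out.data[0][core], x[core], mode="full")
        assert np.argmax(xc) == len(x[core]) - 1  # peak at zero lag

    def test_high_corner_at_nyquist_rejected(self):
        sig = make_signal(np.zeros((1, 512)) + np.random.default_rng(0).normal(size=512), 100.0)
        with pytest.raises(ValueError):
            bandpass(sig, low=1.0, high=50.0)


def narrowband_source(rng, n, rate, f):
    return np.sin(2 * np.pi * f * np.arange(n) / rate + rng.uniform(0, 2 * np.pi))


class TestArtifactCriteria:
    RATE = 256.0
    N = 10 * 256

    def test_heavy_tailed_component_flagged_by_kurtosis_only(self):
        rng = np.random.default_rng(0)
        # sparse blink-like pulses on a smooth carrier: heavy tails, low HF
        # power, lag-1s autocorrelation above threshold
        t = np.arange(self.N) / self.RATE
        spikes = np.zeros(self.N)
        idx = rng.choice(self.N, 10, replace=False)
        spikes[idx] = 30.0
        src = 0.5 * np.sin(2 * np.pi * 2 * t) + sps.lfilter(*sps.butter(2, 0.05), spikes)
        flags = flag_artifact_components(np.ones((4, 1)), src[None, :], self.RATE)
        assert flags[0].kurtosis > 5.0
        assert flags[0].criteria_hit == {1}

    def test_pure_sinusoid_not_flagged(self):
        rng = np.random.default_rng(1)
        src = narrowband_source(rng, self.N, self.RATE, 10.0)
        flags = flag_artifact_components(np.ones((4, 1)), src[None, :], self.RATE)
        f = flags[0]
        assert abs(f.kurtosis - 1.5) < 0.05
        assert f.hf_power_ratio < 0.05
        assert f.lag1s_autocorrelation > 0.9
        assert not f.flagged

    def test_highpassed_noise_flagged_by_hf_ratio(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=self.N)
        sos = sps.butter(6, 35.0, btype="highpass", fs=self.RATE, output="sos")
        src = sps.sosfilt(sos, noise)
        flags = flag_artifact_components(np.ones((4, 1)), src[None, :], self.RATE)
        assert flags[0].hf_power_ratio > 0.4
        assert 2 in flags[0].criteria_hit

    def test_frontal_topography_criterion(self):
        rng = np.random.default_rng(3)
        src = narrowband_source(rng, self.N, self.RATE, 8.0)
        mixing = np.array([[0.5], [0.4], [0.05], [0.05]])
        names = ["Fp1", "Fp2", "Cz", "O1"]
        flags = flag_artifact_components(mixing, src[None, :], self.RATE, names)
        assert flags[0].frontal_weight > 0.7
        assert 3 in flags[0].criteria_hit

    def test_eog_correlation_criterion(self):
        rng = np.random.default_rng(4)
        eog = narrowband_source(rng, self.N, self.RATE, 0.8)
        src = eog + 0.05 * rng.normal(size=self.N)
        flags = flag_artifact_components(np.ones((4, 1)), src[None, :], self.RATE,
                                         eog_reference=eog)
        assert flags[0].eog_correlation > 0.8
        assert 5 in flags[0].criteria_hit

    def test_injected_artifacts_recovered_exactly(self):
        """3 injected artifact sources among 20: the criteria flag exactly
        those three, across 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            # integer frequencies keep the clean rhythms periodic at the
            # 1-second autocorrelation lag
            sources = [narrowband_source(rng, self.N, self.RATE,
                                         float(rng.integers(4, 21)))
                       for _ in range(17)]
            # artifact 1: heavy-tailed blink-like
            t = np.arange(self.N) / self.RATE
            spikes = np.zeros(self.N)
            spikes[rng.choice(self.N, 10, replace=False)] = 30.0
            art1 = 0.5 * np.sin(2 * np.pi * 1.5 * t) + sps.lfilter(*sps.butter(2, 0.05), spikes)
            # artifact 2: EMG-like high-frequency noise
            sos = sps.butter(6, 35.0, btype="highpass", fs=self.RATE, output="sos")
            art2 = sps.sosfilt(sos, rng.normal(size=self.N))
            # artifact 3: white noise (low lag-1s autocorrelation)
            art3 = rng.normal(size=self.N)
            all_sources = np.stack(sources + [art1, art2, art3])
            order = rng.permutation(20)
            injected = {int(np.where(order == k)[0][0]) for k in (17, 18, 19)}
            flags = flag_artifact_components(np.ones((23, 20)),
                                             all_sources[order], self.RATE)
            flagged = {f.index for f in flags if f.flagged}
            assert flagged == injected

    def test_too_short_for_autocorrelation_errors(self):
        with pytest.raises(ValueError):
            flag_artifact_components(np.ones((2, 1)), np.zeros((1, 100)), 256.0)


class TestZScore:
    def test_interictal_statistics_define_the_scale(self):
        rng = np.random.default_rng(0)
        data = rng.normal(3.0, 2.0, size=(2, 4096))
        sig = make_signal(data, 256.0)
        mask = np.zeros(4096, dtype=bool)
        mask[:2048] = True
        out = zscore_interictal(sig, mask)
        assert abs(out.data[:, mask].mean()) < 0.02
        assert 0.98 < out.data[:, mask].std() < 1.02

    def test_constant_channel_raises_named_error(self):
        data = np.vstack([np.zeros(1024) + 2.0,
                          np.random.default_rng(0).normal(size=1024)])
        sig = make_signal(data, 256.0, names=["flatline", "ok"])
        with pytest.raises(ValueError, match="flatline"):
            zscore_interictal(sig, np.ones(1024, dtype=bool))

    def test_no_leakage_of_ictal_statistics(self):
        """Large ictal samples must not shrink the interictal scale, unlike
        the deliberately wrong whole-signal z-scoring."""
        rng = np.random.default_rng(1)
        inter = rng.normal(0, 1, 4096)
        ictal = rng.normal(0, 10, 1024)
        data = np.concatenate([inter, ictal])[None, :]
        sig = make_signal(data, 256.0)
        mask = np.zeros(data.shape[1], dtype=bool)
        mask[:4096] = True
        out = zscore_interictal(sig, mask)
        wrong = (data - data.mean()) / data.std()
        ratio_ok = out.data[0, 4096:].std() / out.data[0, :4096].std()
        ratio_wrong = wrong[0, 4096:].std() / wrong[0, :4096].std()
        assert abs(ratio_ok - 10.0) < 0.5
        assert abs(out.data[0, :4096].std() - 1.0) < 0.02
        assert ratio_ok == pytest.approx(ratio_wrong, rel=1e-6)  # ratios agree,
        # but only the masked version keeps the interictal scale at unity
        assert abs(wrong[0, :4096].std() - 1.0) > 0.5

    def test_zscoring_is_idempotent(self):
        rng = np.random.default_rng(2)
        sig = make_signal(rng.normal(2.0, 3.0, size=(3, 2048)), 256.0)
        mask = np.ones(2048, dtype=bool)
        once = zscore_interictal(sig, mask)
        twice = zscore_interictal(once, mask)
        assert np.abs(twice.data - once.data).max() < 1e-10


class TestPipeline:
    def test_fixed_order_pipeline_produces_finite_zscored_output(self):
        rng = np.random.default_rng(3)
        t = np.arange(8192) / 512.0
        data = np.stack([np.sin(2 * np.pi * f * t) + 0.1 * rng.normal(size=t.size)
                         for f in (4, 7, 10, 13, 21)])
        sig = make_signal(data, 512.0)
        out, flags = preprocess_pipeline(sig, use_ica=True, n_components=5)
        assert out.sampling_rate == 256.0
        assert np.all(np.isfinite(out.data))
        assert abs(out.data.mean(axis=1)).max() < 0.05
        assert len(flags) == 5
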