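"""Spectral estimation, autocorrelation fitting, peak metrics and E1 periods."""

import numpy as np
import pytest

import eodscene as es
from eodscene.spectral import SpectralEstimate

from conftest import BEAT


def _sinusoid(freq=64.0, duration=12.0, rate=2000.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return es.TimeSeries(amp * np.sin(2 * np.pi * freq * t), rate)


class TestPowerSpectrum:
    def test_sinusoid_peak_and_parseval(self):
        psd = es.power_spectrum(_sinusoid(), segment_seconds=2.0)
        assert psd.argmax_frequency() == pytest.approx(64.0, abs=0.5)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(0.5, rel=0.05)

    def test_white_noise_flat_density(self):
        rng = np.random.default_rng(0)
        x = es.TimeSeries(rng.standard_normal(200_000), 2000.0)
        psd = es.power_spectrum(x, segment_seconds=1.0)
        expected = 1.0 / 1000.0  # variance 1 spread over the Nyquist band
        sel = psd.frequencies > 5.0
        assert np.mean(psd.power[sel]) == pytest.approx(expected, rel=0.1)

    def test_oup_lorentzian_half_power(self):
        """The OUP spectrum is Lorentzian with half power at 1/(2 pi tau_c)."""
        tau = 0.5
        cfg = es.SignalConfig(duration=600.0, sample_rate=500.0, rng_seed=2)
        xi = es.generate_oup(tau, cfg)
        psd = es.power_spectrum(xi, segment_seconds=50.0)
        low = np.mean(psd.power[(psd.frequencies > 0.0) & (psd.frequencies < 0.1)])
        f_half = 1.0 / (2 * np.pi * tau)
        at_half = np.interp(f_half, psd.frequencies, psd.power)
        assert at_half / low == pytest.approx(0.5, abs=0.1)

    def test_segment_longer_than_record_raises(self):
        with pytest.raises(ValueError):
            es.power_spectrum(_sinusoid(duration=1.0), segment_seconds=2.0)


class TestSpectrogram:
    def test_static_scene_constant_tracks(self):
        cfg = es.SignalConfig(duration=4.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=0)
        sig, _ = es.synthesize_composite(
            [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.3)], cfg
        )
        f, t, a = es.spectrogram(sig, window_seconds=0.5, step_seconds=0.1)
        for eodf, amp in ((827.0, 1.0), (763.0, 0.3)):
            track = es.asd_track(f, a, eodf)
            assert np.ptp(track) / np.mean(track) < 0.05

    def test_amplitude_step_located(self):
        rate = 2000.0
        t = np.arange(int(4.0 * rate)) / rate
        amp = np.where(t < 2.0, 1.0, 2.0)
        sig = es.TimeSeries(amp * np.sin(2 * np.pi * 200.0 * t), rate)
        f, times, a = es.spectrogram(sig, window_seconds=0.25, step_seconds=0.05)
        track = es.asd_track(f, a, 200.0)
        jump = times[np.argmax(np.diff(track))]
        assert jump == pytest.approx(2.0, abs=0.3)

    def test_moving_fish_track_follows_e2(self, two_fish_scene):
        """The spectrogram amplitude at the neighbour's EODf varies like E2."""
        sig, e2 = two_fish_scene["signal"], two_fish_scene["e2"]
        f, t, a = es.spectrogram(sig, window_seconds=0.5, step_seconds=0.1)
        track = es.asd_track(f, a, 763.0)
        e2_on_t = np.interp(t, e2.times, e2.samples)
        assert np.corrcoef(track, e2_on_t)[0, 1] > 0.9

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            es.spectrogram(_sinusoid(), window_seconds=0.0)


class TestAutocorrelation:
    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        n = 60_000
        x = es.TimeSeries(rng.standard_normal(n), 2000.0)
        lags, acf = es.autocorrelation(x, max_lag=0.05, segment_seconds=30.0)
        assert acf[0] == pytest.approx(1.0)
        assert np.max(np.abs(acf[1:])) < 3.0 / np.sqrt(n / 2)

    def test_periodic_series(self):
        lags, acf = es.autocorrelation(_sinusoid(freq=10.0), max_lag=0.2, segment_seconds=4.0)
        k = int(round(0.1 * 2000))  # one 10 Hz period
        assert acf[k] == pytest.approx(1.0, abs=0.01)

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            es.autocorrelation(_sinusoid(duration=4.0), max_lag=5.0, segment_seconds=4.0)


class TestOUPFit:
    def test_exact_exponential_recovered(self):
        lags = np.arange(0, 3.0, 0.01)
        tau, resid = es.fit_oup_correlation_time(lags, np.exp(-lags / 0.7))
        assert tau == pytest.approx(0.7, abs=1e-3)
        assert resid < 1e-6

    def test_non_decaying_acf_raises(self):
        lags = np.arange(0, 1.0, 0.01)
        with pytest.raises(ValueError):
            es.fit_oup_correlation_time(lags, np.full(lags.size, 0.9))

    def test_tau_ordering_through_full_chain(self):
        """Scenes with slower motion give larger fitted correlation times."""
        estimates = {}
        for tau_c in (0.2, 2.0):
            vals = []
            for seed in range(3):
                srcs = [
                    es.EODSourceSpec(827.0),
                    es.EODSourceSpec(763.0, 0.143, 0.56, motion_correlation_time=tau_c),
                ]
                cfg = es.SignalConfig(60.0, es.FAST_SAMPLE_RATE, rng_seed=30 + seed)
                sig, _ = es.synthesize_composite(srcs, cfg)
                pair = es.extract_envelopes(sig)
                lags, acf = es.autocorrelation(pair.e2, max_lag=3 * tau_c + 0.5,
                                               segment_seconds=60.0)
                vals.append(es.fit_oup_correlation_time(lags, acf)[0])
            estimates[tau_c] = np.mean(vals)
        assert estimates[0.2] < estimates[2.0]


class TestPeakMetrics:
    def test_constructed_gaussian_peak(self):
        f = np.arange(0.0, 200.0, 0.5)
        height, center, sd = 4.0, 64.0, 2.0
        p = height * np.exp(-0.5 * ((f - center) / sd) ** 2) + 1e-4
        spec = SpectralEstimate(f, p, 2.0, 10)
        ref = height * np.exp(-0.5 * 4.0)  # level at center +/- 2 sd
        m = es.peak_metrics(spec, 64.0, ref)
        assert m.center == pytest.approx(center, abs=0.5)
        assert m.height == pytest.approx(height, rel=0.01)
        assert m.width == pytest.approx(4 * sd, abs=0.5)
        assert m.resolution == pytest.approx(m.height / m.width)

    def test_invariant_to_distant_component(self):
        f = np.arange(0.0, 400.0, 0.5)
        peak = 4.0 * np.exp(-0.5 * ((f - 64.0) / 2.0) ** 2) + 1e-4
        far = 8.0 * np.exp(-0.5 * ((f - 200.0) / 2.0) ** 2)
        ref = 0.5
        m0 = es.peak_metrics(SpectralEstimate(f, peak, 2.0, 10), 64.0, ref)
        m1 = es.peak_metrics(SpectralEstimate(f, peak + far, 2.0, 10), 64.0, ref)
        assert m1.height == pytest.approx(m0.height, rel=0.01)
        assert m1.width == pytest.approx(m0.width, rel=0.01)

    def test_reference_above_peak_raises(self):
        f = np.arange(0.0, 200.0, 0.5)
        p = np.exp(-0.5 * ((f - 64.0) / 2.0) ** 2)
        with pytest.raises(ValueError):
            es.peak_metrics(SpectralEstimate(f, p, 2.0, 10), 64.0, 2.0)


class TestE1Periods:
    def test_noiseless_beat_periods(self):
        cfg = es.SignalConfig(duration=8.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=0)
        sig, _ = es.synthesize_composite(
            [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.2)], cfg
        )
        stats = es.e1_periods(es.extract_e1(sig))
        assert stats.mode == pytest.approx(1.0 / BEAT, abs=0.02e-3)
        assert stats.cv < 0.01
        assert np.allclose(stats.periods, 1.0 / BEAT, atol=0.1e-3)

    def test_too_few_crossings_raise(self):
        const = es.TimeSeries(np.ones(4000), es.FAST_SAMPLE_RATE)
        with pytest.raises(ValueError):
            es.e1_periods(const)


class TestFullChainProperties:
    @pytest.mark.parametrize("df,a2", [(20.0, 0.07), (64.0, 0.143), (150.0, 0.2)])
    def test_beat_identification(self, df, a2):
        """E1 spectral argmax equals the beat frequency for any two-fish scene
        in the behaviourally relevant parameter range."""
        srcs = [es.EODSourceSpec(827.0), es.EODSourceSpec(827.0 - df, a2, 0.56)]
        cfg = es.SignalConfig(12.0, es.FAST_SAMPLE_RATE, rng_seed=int(df))
        sig, _ = es.synthesize_composite(srcs, cfg)
        psd = es.power_spectrum(es.extract_e1(sig), segment_seconds=2.0)
        assert psd.argmax_frequency(5.0, 300.0) == pytest.approx(df, abs=0.5)

    def test_motion_floor(self):
        """Swimming adds >=10x more 0-20 Hz power to E1 than the static case."""
        powers = {}
        for sigma in (0.0, 0.56):
            srcs = [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.143, sigma)]
            cfg = es.SignalConfig(12.0, es.FAST_SAMPLE_RATE, rng_seed=40)
            sig, _ = es.synthesize_composite(srcs, cfg)
            psd = es.power_spectrum(es.extract_e1(sig), segment_seconds=2.0)
            powers[sigma] = es.band_power(psd, 0.5, 20.0)
        assert powers[0.56] > 10.0 * powers[0.0]
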