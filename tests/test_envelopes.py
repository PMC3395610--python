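"""Envelope extraction, contrast statistics and the small-amplitude AM theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eodscene as es
from eodscene.envelopes import local_maxima

from conftest import BEAT, two_fish_sources


def _fast_cfg(duration=4.0, seed=0):
    return es.SignalConfig(duration=duration, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=seed)


class TestExtractE1:
    def test_pure_sinusoid_constant_envelope(self):
        cfg = _fast_cfg()
        sig, _ = es.synthesize_composite([es.EODSourceSpec(827.0)], cfg)
        e1 = es.extract_e1(sig)
        assert np.max(np.abs(e1.interior() - 1.0)) < 0.01

    def test_two_static_fish_beat_frequency(self):
        cfg = _fast_cfg()
        sig, _ = es.synthesize_composite(
            [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.143)], cfg
        )
        e1 = es.extract_e1(sig)
        psd = es.power_spectrum(e1, segment_seconds=2.0)
        assert psd.argmax_frequency(5.0, 300.0) == pytest.approx(BEAT, abs=0.5)

    def test_sam_modulator_recovered(self):
        cfg = _fast_cfg()
        sam = es.generate_sam(827.0, 0.3, 64.0, cfg)
        e1 = es.extract_e1(sam)
        t = cfg.times
        expected = 1.0 + 0.3 * np.sin(2 * np.pi * 64.0 * t)
        k = int(0.05 * cfg.sample_rate)
        rms = np.sqrt(np.mean((e1.samples[k:-k] - expected[k:-k]) ** 2))
        assert rms < 0.01

    def test_eodf_power_removed(self, two_fish_scene):
        """E1 keeps no power at the EOD fundamentals above -60 dB relative to
        the beat peak (the low-pass removes the remnant EODf line)."""
        e1 = two_fish_scene["e1"]
        fluct = es.TimeSeries(e1.samples - e1.samples.mean(), e1.sample_rate)
        psd = es.power_spectrum(fluct, segment_seconds=2.0)
        beat_peak = psd.power[np.argmin(np.abs(psd.frequencies - BEAT))]
        for f_eod in (763.0, 827.0):
            at_eod = psd.power[np.argmin(np.abs(psd.frequencies - f_eod))]
            assert at_eod < 1e-6 * beat_peak

    def test_too_short_input_raises(self):
        tiny = es.TimeSeries(np.sin(np.arange(10)), es.FAST_SAMPLE_RATE)
        with pytest.raises(ValueError):
            es.extract_e1(tiny)


class TestExtractE2:
    def test_static_beat_gives_constant_e2(self):
        cfg = _fast_cfg()
        sig, _ = es.synthesize_composite(
            [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.143)], cfg
        )
        pair = es.extract_envelopes(sig)
        e2 = pair.e2.interior()
        assert np.ptp(e2) / np.mean(e2) < 0.05

    def test_three_static_fish_secondary_beat(self, three_fish_scene):
        psd = es.power_spectrum(three_fish_scene["e2"], segment_seconds=2.0)
        assert psd.argmax_frequency(5.0, 300.0) == pytest.approx(33.0, abs=0.5)

    def test_e2_tracks_ground_truth_amplitude(self):
        """E2 of a moving two-fish scene follows the neighbour's amplitude
        trace (Pearson r > 0.95 over 10 s at default parameters)."""
        cfg = es.SignalConfig(duration=10.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=21)
        sig, amps = es.synthesize_composite(two_fish_sources(), cfg)
        pair = es.extract_envelopes(sig)
        k = int(0.05 * cfg.sample_rate)
        r = np.corrcoef(pair.e2.samples[k:-k], amps[1][k:-k])[0, 1]
        assert r > 0.95

    def test_window_validation(self):
        cfg = _fast_cfg(duration=1.0)
        sig, _ = es.synthesize_composite([es.EODSourceSpec(827.0)], cfg)
        e1 = es.extract_e1(sig)
        with pytest.raises(ValueError):
            es.extract_e2(e1, window=1e-5)


class TestDirectEnvelope:
    def test_pure_sinusoid(self):
        cfg = _fast_cfg(duration=1.0)
        sig, _ = es.synthesize_composite([es.EODSourceSpec(827.0)], cfg)
        env = es.extract_envelope_direct(sig)
        assert np.max(np.abs(env.interior() - 1.0)) < 0.02

    def test_agrees_with_hilbert_envelope(self, two_fish_scene):
        """Peak-connection and analytic-signal E1 agree within 5% normalized
        RMS away from the edges."""
        direct = es.extract_envelope_direct(two_fish_scene["signal"])
        hilb = two_fish_scene["e1"]
        k = int(0.1 * hilb.sample_rate)
        d, h = direct.samples[k:-k], hilb.samples[k:-k]
        nrms = np.sqrt(np.mean((d - h) ** 2)) / np.mean(h)
        assert nrms < 0.05

    def test_sam_tracking(self):
        cfg = _fast_cfg()
        sam = es.generate_sam(827.0, 0.5, 10.0, cfg)
        env = es.extract_envelope_direct(sam)
        t = cfg.times
        expected = 1.0 + 0.5 * np.sin(2 * np.pi * 10.0 * t)
        k = int(0.05 * cfg.sample_rate)
        assert np.max(np.abs(env.samples[k:-k] - expected[k:-k])) < 0.02 * 1.5

    def test_needs_three_maxima(self):
        flat = es.TimeSeries(np.linspace(0, 1, 100), 1000.0)
        with pytest.raises(ValueError):
            es.extract_envelope_direct(flat)


class TestInstantaneousContrast:
    @pytest.mark.parametrize("depth", [0.05, 0.1, 0.3, 0.5])
    def test_sam_contrast_equals_depth(self, depth):
        cfg = _fast_cfg()
        e1 = es.extract_e1(es.generate_sam(827.0, depth, 64.0, cfg))
        stats = es.instantaneous_contrast(e1)
        assert stats.mean_contrast == pytest.approx(depth, rel=0.01)
        assert stats.sd_contrast < 0.01 * max(depth, 0.1)

    def test_constant_envelope_raises(self):
        const = es.TimeSeries(np.ones(10_000), es.FAST_SAMPLE_RATE)
        with pytest.raises(ValueError):
            es.instantaneous_contrast(const)

    def test_model_scene_matches_theory(self):
        """On a 60 s moving scene the contrast mean tracks A2 and the SD
        tracks A2*sigma2 (single-seed check; the multi-seed average against
        theory lives in the acceptance suite)."""
        cfg = es.SignalConfig(duration=60.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=13)
        sig, _ = es.synthesize_composite(two_fish_sources(), cfg)
        stats = es.instantaneous_contrast(es.extract_e1(sig))
        assert stats.mean_contrast == pytest.approx(0.143, abs=0.02)
        assert stats.sd_contrast == pytest.approx(0.080, abs=0.02)


class TestPredictAM:
    def test_representative_pair(self):
        mean_c, sd_c, desc = es.predict_am(two_fish_sources())
        assert mean_c == pytest.approx(0.143)
        assert sd_c == pytest.approx(0.143 * 0.56)
        assert "cos" in desc

    def test_static_neighbour_has_zero_sd(self):
        mean_c, sd_c, _ = es.predict_am(
            [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.2, 0.0)]
        )
        assert sd_c == 0.0

    def test_large_amplitude_warns(self):
        with pytest.warns(UserWarning):
            es.predict_am([es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.6, 0.1)])

    def test_from_contrast_convention(self):
        spec = es.EODSourceSpec.from_contrast(763.0, 0.143, 0.08)
        assert spec.mean_amplitude == pytest.approx(0.143)
        assert spec.amplitude_sd == pytest.approx(0.08 / 0.143)


class TestLocalMaxima:
    def test_plateau_takes_left_sample(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 2.0, 0.0])
        assert list(local_maxima(x)) == [1, 5]

    def test_monotone_has_none(self):
        assert local_maxima(np.arange(5.0)).size == 0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_envelopes_are_amplitude_equivariant(scale):
    """Scaling the input by c scales E1 and E2 by c and leaves the contrast
    statistics unchanged."""
    cfg = es.SignalConfig(duration=3.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=17)
    sig, _ = es.synthesize_composite(two_fish_sources(), cfg)
    base = es.extract_envelopes(sig)
    scaled = es.extract_envelopes(sig.scaled(scale))
    assert np.allclose(scaled.e1.samples, scale * base.e1.samples, rtol=1e-9, atol=1e-12)
    assert np.allclose(scaled.e2.samples, scale * base.e2.samples, rtol=1e-9, atol=1e-12)
    c0 = es.instantaneous_contrast(base.e1)
    c1 = es.instantaneous_contrast(scaled.e1)
    assert c1.mean_contrast == pytest.approx(c0.mean_contrast, rel=1e-9)
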