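"""Shared fixtures: small synthetic scenes and calibrated P-units.

Scene fixtures use the 20 kHz fast rate where only envelope content matters;
anything driving the P-unit model runs on the native 100 kHz grid (0.01 ms
integration step).  Expensive calibrations are session-scoped and shared.
"""

import pytest

import eodscene as es

#: Representative two-fish interaction: receiver 827 Hz, neighbour 763 Hz,
#: mean contrast 0.143 and contrast SD 0.08 (sigma = 0.56).
F1, F2 = 827.0, 763.0
A2, SIGMA2 = 0.143, 0.56
BEAT = F1 - F2  # 64 Hz


def two_fish_sources(a2: float = A2, sigma2: float = SIGMA2) -> list[es.EODSourceSpec]:
    return [es.EODSourceSpec(F1), es.EODSourceSpec(F2, a2, sigma2)]


def three_fish_static_sources() -> list[es.EODSourceSpec]:
    return [
        es.EODSourceSpec(831.0),
        es.EODSourceSpec(740.0, 0.143),
        es.EODSourceSpec(889.0, 0.143),
    ]


@pytest.fixture(scope="session")
def two_fish_scene():
    """12 s moving two-fish scene at the fast rate, with envelopes."""
    cfg = es.SignalConfig(duration=12.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=1)
    signal, amplitudes = es.synthesize_composite(two_fish_sources(), cfg)
    pair = es.extract_envelopes(signal)
    return {"signal": signal, "amplitudes": amplitudes, "e1": pair.e1, "e2": pair.e2}


@pytest.fixture(scope="session")
def three_fish_scene():
    """12 s static three-fish scene (beats 91 and 58 Hz, secondary 33 Hz)."""
    cfg = es.SignalConfig(duration=12.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=2)
    signal, amplitudes = es.synthesize_composite(three_fish_static_sources(), cfg)
    pair = es.extract_envelopes(signal)
    return {"signal": signal, "amplitudes": amplitudes, "e1": pair.e1, "e2": pair.e2}


@pytest.fixture(scope="session")
def calibrated_units():
    """LIFDT parameter sets calibrated to P-values 0.12, 0.26 and 0.40."""
    return {
        p: es.calibrate_noise_for_pvalue(p, F1, calibration_seed=1000 + i)
        for i, p in enumerate((0.12, 0.26, 0.40))
    }


@pytest.fixture(scope="session")
def population_200():
    """The default heterogeneous 200-unit population (calibrated once)."""
    return es.sample_population(n=200, eodf=F1, master_seed=7)
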