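"""Synthetic multi-fish EOD scenes.

A weakly electric fish receives the superposition of its own electric organ
discharge (EOD) and those of nearby conspecifics.  With constant discharge
frequencies the composite signal at the receiving fish's skin is modelled as

    S(t) = sum_n  A_n (1 + sigma_n xi_n(t)) sin(2 pi f_n t + phi_n)

where fish ``n = 1`` is the receiving fish (amplitude fixed at 1, no
fluctuation) and each free-swimming neighbour contributes a sinusoid at its
own EOD frequency ``f_n`` whose amplitude wanders around ``A_n`` as the fish
moves.  The wandering is modelled by a zero-mean, unit-variance
Ornstein-Uhlenbeck process ``xi_n`` scaled by ``sigma_n``: low-pass Gaussian
noise whose correlation time ``tau_c`` sets how smooth the swimming-induced
amplitude changes are.

This module also produces the two laboratory mimics of such scenes —
sinusoidal amplitude modulation (SAM) and narrowband random amplitude
modulation (RAM) of a carrier — used to probe electroreceptor models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import SignalConfig, TimeSeries

__all__ = [
    "EODSourceSpec",
    "generate_oup",
    "synthesize_composite",
    "generate_sam",
    "generate_narrowband_ram",
    "DEFAULT_MOTION_CORRELATION_TIME",
]

#: Default OUP correlation time in seconds.  This is a package configuration
#: choice (envelope autocorrelations of free-swimming pairs decay over
#: roughly a second), not an empirically fitted constant.
DEFAULT_MOTION_CORRELATION_TIME = 0.5


@dataclass
class EODSourceSpec:
    """EOD parameters for one fish in the scene.

    Attributes
    ----------
    eod_frequency : float
        Fundamental EOD frequency in Hz (700–1100 Hz for *A. leptorhynchus*).
    mean_amplitude : float
        Mean amplitude ``A_n`` at the receiving fish's skin, in units of the
        receiving fish's own EOD amplitude (which is fixed at 1).
    amplitude_sd : float
        Scale ``sigma_n`` of the relative amplitude fluctuation; 0 for a
        static fish.
    motion_correlation_time : float
        OUP correlation time ``tau_c`` in seconds.
    phase : float
        Initial phase in radians.  Phase does not affect envelope spectra
        and defaults to 0.
    """

    eod_frequency: float
    mean_amplitude: float = 1.0
    amplitude_sd: float = 0.0
    motion_correlation_time: float = DEFAULT_MOTION_CORRELATION_TIME
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.eod_frequency <= 0:
            raise ValueError("eod_frequency must be positive")
        if self.mean_amplitude < 0:
            raise ValueError("mean_amplitude must be nonnegative")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be nonnegative")
        if self.motion_correlation_time <= 0:
            raise ValueError("motion_correlation_time must be positive")

    @classmethod
    def from_contrast(
        cls,
        eod_frequency: float,
        mean_contrast: float,
        sd_contrast: float,
        motion_correlation_time: float = DEFAULT_MOTION_CORRELATION_TIME,
        phase: float = 0.0,
    ) -> "EODSourceSpec":
        """Build a neighbour spec from measured contrast statistics.

        For a weak neighbour the mean and SD of the instantaneous beat
        contrast equal ``A_n`` and ``A_n * sigma_n``, so a measured pair
        (mean contrast, SD of contrast) maps to ``A_n = mean`` and
        ``sigma_n = sd / mean``.  This is the convention used for the
        representative two-fish pair (0.143, 0.08), giving sigma ≈ 0.56.
        """
        if mean_contrast <= 0:
            raise ValueError("mean_contrast must be positive")
        return cls(
            eod_frequency=eod_frequency,
            mean_amplitude=mean_contrast,
            amplitude_sd=sd_contrast / mean_contrast,
            motion_correlation_time=motion_correlation_time,
            phase=phase,
        )


def _source_rng(seed: int, index: int) -> np.random.Generator:
    # Fixed per-source child streams: adding a fish never perturbs the
    # realizations of the others.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_oup(
    motion_correlation_time: float,
    config: SignalConfig,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Sample a stationary Ornstein-Uhlenbeck process on the config grid.

    The process has zero mean, unit variance and autocorrelation
    ``exp(-|lag| / tau_c)``.  The exact AR(1) discretization

        xi[k+1] = xi[k] * exp(-dt/tau_c) + sqrt(1 - exp(-2 dt/tau_c)) * z[k]

    is used (rather than Euler–Maruyama) so the stationary variance is exact
    at any step size; the initial value is drawn from the stationary N(0, 1)
    distribution.
    """
    if motion_correlation_time <= 0:
        raise ValueError("motion_correlation_time must be positive")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples
    alpha = float(np.exp(-config.dt / motion_correlation_time))
    innovation_sd = float(np.sqrt(max(0.0, 1.0 - alpha * alpha)))
    w = rng.standard_normal(n)
    w[1:] *= innovation_sd
    # xi[k] = alpha * xi[k-1] + w[k] with xi[0] = w[0] ~ N(0,1)
    xi = lfilter([1.0], [1.0, -alpha], w)
    return TimeSeries(xi, config.sample_rate)


def synthesize_composite(
    sources: list[EODSourceSpec], config: SignalConfig
) -> tuple[TimeSeries, np.ndarray]:
    """Synthesize the composite EOD signal received by fish 1.

    Parameters
    ----------
    sources : list of EODSourceSpec
        The first entry is the receiving fish: ``mean_amplitude`` 1 and
        ``amplitude_sd`` 0 are required.  Remaining entries are neighbours.
    config : SignalConfig
        Duration, rate and master seed.  Each moving fish gets an
        independent OUP stream derived from the seed.

    Returns
    -------
    (signal, amplitudes)
        ``signal`` is S(t); ``amplitudes`` is an ``(n_sources, n_samples)``
        array of the instantaneous amplitude ``A_n (1 + sigma_n xi_n(t))``
        of every source — the ground truth the extracted second envelope is
        validated against.  Amplitudes are not clipped at zero; envelope
        analysis sees the magnitude of whatever the model produces.
    """
    if not sources:
        raise ValueError("at least one EOD source (the receiving fish) is required")
    first = sources[0]
    if first.mean_amplitude != 1.0 or first.amplitude_sd != 0.0:
        raise ValueError(
            "the first source is the receiving fish and must have "
            "mean_amplitude=1 and amplitude_sd=0"
        )
    f_max = max(s.eod_frequency for s in sources)
    if config.sample_rate <= 2.0 * f_max:
        raise ValueError(
            f"sample_rate {config.sample_rate} Hz violates Nyquist for "
            f"EOD frequency {f_max} Hz"
        )
    t = config.times
    signal = np.zeros_like(t)
    amplitudes = np.empty((len(sources), t.size))
    for i, src in enumerate(sources):
        if src.amplitude_sd > 0:
            xi = generate_oup(
                src.motion_correlation_time, config, rng=_source_rng(config.rng_seed, i)
            ).samples
            amp = src.mean_amplitude * (1.0 + src.amplitude_sd * xi)
        else:
            amp = np.full(t.size, src.mean_amplitude)
        amplitudes[i] = amp
        signal += amp * np.sin(2.0 * np.pi * src.eod_frequency * t + src.phase)
    return TimeSeries(signal, config.sample_rate), amplitudes


def generate_sam(
    carrier_frequency: float,
    depth: float,
    modulation_frequency: float,
    config: SignalConfig,
) -> TimeSeries:
    """Sinusoidally amplitude-modulated carrier ``(1 + M sin(2pi f_m t)) sin(2pi f_c t)``.

    The contrast (coefficient of variation of the AM) of a SAM equals its
    depth ``M``, independent of the modulation frequency.
    """
    if not 0.0 <= depth < 1.0:
        raise ValueError("SAM depth must be in [0, 1); the envelope would rectify")
    if modulation_frequency >= carrier_frequency / 2.0:
        raise ValueError("modulation_frequency must be below carrier_frequency/2")
    if config.sample_rate <= 2.0 * carrier_frequency:
        raise ValueError("sample rate violates Nyquist for the carrier")
    t = config.times
    am = 1.0 + depth * np.sin(2.0 * np.pi * modulation_frequency * t)
    return TimeSeries(am * np.sin(2.0 * np.pi * carrier_frequency * t), config.sample_rate)


def generate_narrowband_ram(
    carrier_frequency: float,
    band_low: float,
    band_high: float,
    contrast: float,
    config: SignalConfig,
    rng: np.random.Generator | None = None,
    return_modulator: bool = False,
):
    """Carrier with a narrowband Gaussian random amplitude modulation.

    The modulator ``m(t)`` is zero-mean Gaussian noise whose power is
    confined to ``[band_low, band_high]`` Hz (hard spectral truncation) and
    scaled so that the AM ``1 + m(t)`` has coefficient of variation equal to
    ``contrast``.  A 70–120 Hz band mimics the beats of a group of static
    conspecifics without any low-frequency motion power.
    """
    if not 0.0 < band_low < band_high:
        raise ValueError("need 0 < band_low < band_high")
    if band_high >= carrier_frequency / 2.0:
        raise ValueError("modulation band must lie below carrier_frequency/2")
    if config.sample_rate <= 2.0 * carrier_frequency:
        raise ValueError("sample rate violates Nyquist for the carrier")
    if contrast < 0:
        raise ValueError("contrast must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    t = config.times
    n = t.size
    if contrast == 0.0:
        m = np.zeros(n)
    else:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=config.dt)
        spec[(freqs < band_low) | (freqs > band_high)] = 0.0
        m = np.fft.irfft(spec, n=n)
        m *= contrast / np.std(m)
    carrier = np.sin(2.0 * np.pi * carrier_frequency * t)
    out = TimeSeries((1.0 + m) * carrier, config.sample_rate)
    if return_modulator:
        return out, TimeSeries(m, config.sample_rate)
    return out
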