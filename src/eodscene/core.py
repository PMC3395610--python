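"""Core containers: uniformly sampled time series and generation settings.

Everything downstream (scene synthesis, envelopes, spectra, spike metrics)
passes signals around as :class:`TimeSeries` — a plain array with a sample
rate — so that sample-rate bookkeeping errors fail loudly instead of
silently misaligning frequency axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries", "SignalConfig", "DEFAULT_SAMPLE_RATE", "FAST_SAMPLE_RATE"]

#: Default sampling rate, matching 100 kHz tank-recording hardware and the
#: 0.01 ms integration step of the electroreceptor model.
DEFAULT_SAMPLE_RATE = 100_000.0

#: Reduced rate for envelope-only analyses where nothing above a few hundred
#: hertz matters (carrier < 1.1 kHz, Nyquist 10 kHz is ample).
FAST_SAMPLE_RATE = 20_000.0


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Signal values; coerced to float64, must be finite.
    sample_rate : float
        Samples per second (Hz).
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("TimeSeries samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("TimeSeries samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def interior(self, margin: float = 0.05) -> np.ndarray:
        """Samples with ``margin`` seconds trimmed from both ends.

        Envelope statistics exclude filter-settling edges; 50 ms covers the
        settling of every filter used in this package.
        """
        k = int(round(margin * self.sample_rate))
        if 2 * k >= self.samples.size:
            raise ValueError(
                f"record of {self.duration:.3f}s too short to trim {margin}s edges"
            )
        return self.samples[k : self.samples.size - k]

    def decimate(self, factor: int) -> "TimeSeries":
        """Keep every ``factor``-th sample (no anti-alias filter).

        Only valid when the series is already band-limited well below the
        decimated Nyquist rate, as envelopes are (≤200 Hz content).
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError("decimation factor must be a positive integer")
        return TimeSeries(
            self.samples[::factor], self.sample_rate / factor, self.start_time
        )

    def scaled(self, c: float) -> "TimeSeries":
        return TimeSeries(self.samples * c, self.sample_rate, self.start_time)


@dataclass
class SignalConfig:
    """Duration, sampling rate and seed for synthesized signals."""

    duration: float
    sample_rate: float = DEFAULT_SAMPLE_RATE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9 * max(n, 1.0):
            raise ValueError(
                f"duration {self.duration}s is not a whole number of samples "
                f"at {self.sample_rate} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate
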