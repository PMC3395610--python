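"""Two-level envelope extraction and beat-contrast statistics.

The composite signal of several fish carries information on two nested time
scales.  The first envelope E1 — the amplitude modulation of the raw signal —
oscillates at the beat frequencies (differences between EOD frequencies).
The second envelope E2 — the envelope of E1 — varies with the slow
swimming-induced amplitude changes and, with three or more fish, with the
secondary beats ("beats of beats").

E1 is the magnitude of the analytic signal (Hilbert transform) followed by a
low-pass filter that removes the residual spectral peak at the EOD
frequency.  E2 applies the same analytic-signal step to E1 over short
windows assembled end to end.  A direct peak-connection envelope is provided
as an independent cross-check of both.

For a weak neighbour (A2 << 1) the AM admits the small-amplitude expansion

    AM(t) ≈ 1 + A2 (1 + sigma2 xi(t)) cos(2 pi (f1 - f2) t),

a random-amplitude beat whose instantaneous contrast has mean ≈ A2 and
SD ≈ A2 * sigma2 (`predict_am`).  The instantaneous contrast of a measured
envelope is computed per beat half-cycle from adjacent extrema:
(H - L)/(H + L) for each local maximum H and the following minimum L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import TimeSeries
from .scenes import EODSourceSpec

__all__ = [
    "EnvelopePair",
    "ContrastStats",
    "extract_e1",
    "extract_e2",
    "extract_envelopes",
    "extract_envelope_direct",
    "instantaneous_contrast",
    "predict_am",
    "EDGE_MARGIN",
]

#: Seconds excluded at each end of an envelope before computing statistics
#: (filter settling).
EDGE_MARGIN = 0.05


@dataclass
class EnvelopePair:
    """First (beat) and second (motion) envelopes of a raw signal."""

    e1: TimeSeries
    e2: TimeSeries


@dataclass
class ContrastStats:
    """Mean and SD of the instantaneous beat contrast.

    ``n_half_cycles`` counts the (maximum, following minimum) pairs used.
    """

    mean_contrast: float
    sd_contrast: float
    n_half_cycles: int


def _lowpass(x: np.ndarray, cutoff: float, sample_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; zero-phase keeps envelope timing."""
    sos = butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError(
            f"record of {x.size} samples too short for the {cutoff} Hz filter"
        )
    return sosfiltfilt(sos, x)


def extract_e1(signal: TimeSeries, lpf_cutoff: float = 200.0) -> TimeSeries:
    """First envelope: analytic-signal magnitude, low-passed at ``lpf_cutoff``.

    The Hilbert-transform envelope of a multi-fish signal retains a remnant
    spectral peak at the EOD frequency; the low-pass (default 200 Hz, well
    above any beat of interest and well below the EOD fundamentals) removes
    it.
    """
    if lpf_cutoff >= signal.sample_rate / 2.0:
        raise ValueError("lpf_cutoff must be below the Nyquist frequency")
    if signal.samples.size < 16:
        raise ValueError("signal too short for envelope extraction")
    env = np.abs(hilbert(signal.samples))
    return TimeSeries(
        _lowpass(env, lpf_cutoff, signal.sample_rate), signal.sample_rate, signal.start_time
    )


def extract_e2(
    e1: TimeSeries, window: float = 0.1, smoothing_cutoff: float = 50.0
) -> TimeSeries:
    """Second envelope: windowed analytic-signal envelope of E1.

    Within each ``window``-second segment the mean beat level is removed,
    the magnitude of the analytic signal of the residual oscillation is
    taken, and the mean is added back; segments are assembled end to end.
    A zero-phase low-pass at ``smoothing_cutoff`` suppresses the
    segment-boundary discontinuities (pass ``None`` to skip it).
    """
    x = e1.samples
    n = x.size
    win = int(round(window * e1.sample_rate))
    if win < 8:
        raise ValueError("E2 window shorter than a resolvable beat period")
    if win > n:
        raise ValueError("E2 window longer than the record")
    out = np.empty_like(x)
    for start in range(0, n, win):
        seg = x[start : start + win]
        if seg.size < 8:
            # short tail: reuse the last full window's level
            out[start:] = out[start - 1]
            break
        mu = seg.mean()
        out[start : start + seg.size] = np.abs(hilbert(seg - mu)) + mu
    if smoothing_cutoff is not None:
        out = _lowpass(out, smoothing_cutoff, e1.sample_rate)
    return TimeSeries(out, e1.sample_rate, e1.start_time)


def extract_envelopes(
    signal: TimeSeries, lpf_cutoff: float = 200.0, window: float = 0.1
) -> EnvelopePair:
    """Convenience: E1 and E2 of a raw signal in one call."""
    e1 = extract_e1(signal, lpf_cutoff)
    return EnvelopePair(e1=e1, e2=extract_e2(e1, window))


def extract_envelope_direct(signal: TimeSeries) -> TimeSeries:
    """Envelope by connecting successive local maxima (peak connection).

    Monotone piecewise-cubic (PCHIP) interpolation through the peaks of
    successive oscillation cycles, evaluated on the input grid.  Serves as
    an independent cross-check of the analytic-signal envelopes.
    """
    x = signal.samples
    peaks = local_maxima(x)
    if peaks.size < 3:
        raise ValueError("fewer than 3 local maxima; cannot connect peaks")
    interp = PchipInterpolator(peaks, x[peaks], extrapolate=False)
    idx = np.arange(x.size, dtype=float)
    env = interp(idx)
    # hold the first/last peak level beyond the outermost peaks
    env[: peaks[0]] = x[peaks[0]]
    env[peaks[-1] :] = x[peaks[-1]]
    return TimeSeries(env, signal.sample_rate, signal.start_time)


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus take the left-most sample.

    A maximum is a rising first difference whose next nonzero first
    difference is falling, so flat stretches between a rise and a fall count
    once, at their left edge (deterministic tie-break).
    """
    d = np.sign(np.diff(x))
    pos = np.flatnonzero(d)
    if pos.size < 2:
        return np.array([], dtype=int)
    signs = d[pos]
    k = np.nonzero((signs[:-1] > 0) & (signs[1:] < 0))[0]
    return pos[k] + 1


def _local_minima(x: np.ndarray) -> np.ndarray:
    return local_maxima(-x)


def instantaneous_contrast(e1: TimeSeries, edge_margin: float = EDGE_MARGIN) -> ContrastStats:
    """Per-half-cycle contrast statistics of a beat envelope.

    For each local maximum ``H`` of E1 and the nearest following local
    minimum ``L``, the instantaneous contrast is ``(H - L) / (H + L)``.
    Returns the mean and SD over all such pairs, excluding ``edge_margin``
    seconds at each end.
    """
    x = e1.interior(edge_margin) if edge_margin > 0 else e1.samples
    maxima = local_maxima(x)
    minima = _local_minima(x)
    if maxima.size == 0 or minima.size == 0:
        raise ValueError("envelope has no max–min pairs (constant or monotone input)")
    # nearest following minimum for each maximum
    pos = np.searchsorted(minima, maxima, side="right")
    valid = pos < minima.size
    if not np.any(valid):
        raise ValueError("no local minimum follows any maximum")
    h = x[maxima[valid]]
    l = x[minima[pos[valid]]]
    contrasts = (h - l) / (h + l)
    return ContrastStats(
        mean_contrast=float(np.mean(contrasts)),
        sd_contrast=float(np.std(contrasts)),
        n_half_cycles=int(contrasts.size),
    )


def predict_am(sources: list[EODSourceSpec]) -> tuple[float, float, str]:
    """Small-amplitude theory for the two-fish AM.

    Returns ``(predicted mean contrast, predicted SD of contrast,
    description)``: for a weak neighbour the AM is approximately
    ``1 + A2 (1 + sigma2 xi(t)) cos(2 pi df t)``, so the instantaneous
    contrast has mean ``A2`` and SD ``A2 * sigma2``.
    """
    if len(sources) != 2:
        raise ValueError("the small-amplitude AM theory applies to two fish")
    receiver, neighbour = sources
    a2 = neighbour.mean_amplitude
    s2 = neighbour.amplitude_sd
    if a2 >= 0.5:
        warnings.warn(
            f"A2 = {a2} is large; the first-order Taylor expansion of the AM "
            "may be inaccurate",
            stacklevel=2,
        )
    df = abs(receiver.eod_frequency - neighbour.eod_frequency)
    desc = (
        f"AM(t) ≈ 1 + {a2:g}·(1 + {s2:g}·ξ(t))·cos(2π·{df:g}·t); "
        "a beat whose amplitude wanders with the neighbour's motion"
    )
    return a2, a2 * s2, desc
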