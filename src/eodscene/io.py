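"""Readers and writers for scenes, envelopes and spike trains.

Scenes go to single-channel float WAV (sample rate in the header) or
two-column delimited text (time, value); spike trains to one spike time per
line; configuration echoes (sources, seeds, correlation times) to YAML
sidecars so a synthesized scene can be re-created or audited later.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .core import TimeSeries
from .punit import SpikeTrain
from .scenes import EODSourceSpec

__all__ = [
    "write_wav",
    "read_wav",
    "write_timeseries_text",
    "read_timeseries_text",
    "write_spike_times",
    "read_spike_times",
    "write_scene_sidecar",
    "read_scene_sidecar",
]


def write_wav(path: str | Path, series: TimeSeries) -> None:
    """Single-channel float32 WAV with the sample rate in the header."""
    wavfile.write(path, int(round(series.sample_rate)), series.samples.astype(np.float32))


def read_wav(path: str | Path) -> TimeSeries:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("expected a single-channel recording")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return TimeSeries(np.asarray(data, dtype=np.float64), float(rate))


def write_timeseries_text(path: str | Path, series: TimeSeries, delimiter: str = "\t") -> None:
    """Two-column (time, value) delimited text."""
    np.savetxt(
        path,
        np.column_stack([series.times, series.samples]),
        delimiter=delimiter,
        header="time_s\tvalue",
        comments="# ",
    )


def read_timeseries_text(path: str | Path, delimiter: str | None = None) -> TimeSeries:
    data = np.loadtxt(path, delimiter=delimiter)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two columns: time, value")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError("time column must be strictly increasing and uniform")
    return TimeSeries(x, 1.0 / dt.mean(), start_time=float(t[0]))


def write_spike_times(path: str | Path, train: SpikeTrain) -> None:
    """One spike time (seconds) per line, with duration in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# duration_s {train.duration}\n# time_step_ms {train.time_step}\n")
        for t in train.spike_times:
            fh.write(f"{t:.6f}\n")


def read_spike_times(path: str | Path) -> SpikeTrain:
    duration = None
    time_step = 0.01
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "duration_s":
                    duration = float(parts[1])
                elif parts and parts[0] == "time_step_ms":
                    time_step = float(parts[1])
            elif line:
                times.append(float(line))
    times_arr = np.array(times)
    if duration is None:
        duration = float(times_arr[-1]) if times_arr.size else 0.0
    return SpikeTrain(times_arr, duration=duration, time_step=time_step)


def write_scene_sidecar(
    path: str | Path, sources: list[EODSourceSpec], seed: int, sample_rate: float, duration: float
) -> None:
    """YAML echo of the generating configuration (ground truth for audits)."""
    doc = {
        "sources": [asdict(s) for s in sources],
        "rng_seed": int(seed),
        "sample_rate": float(sample_rate),
        "duration": float(duration),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scene_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["sources"] = [EODSourceSpec(**s) for s in doc["sources"]]
    return doc
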