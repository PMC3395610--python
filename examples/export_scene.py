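"""Writing a synthesized scene to disk with its ground-truth sidecar.

Scenes go to float WAV (or two-column text) plus a YAML sidecar echoing the
generating configuration, so a recording can be re-created bit-identically
or audited later.
"""

from pathlib import Path

import eodscene as es
from eodscene import io

out = Path("scratch/export_scene")
out.mkdir(parents=True, exist_ok=True)

sources = [es.EODSourceSpec(827.0), es.EODSourceSpec(763.0, 0.143, 0.56)]
cfg = es.SignalConfig(duration=2.0, sample_rate=es.FAST_SAMPLE_RATE, rng_seed=7)
signal, _ = es.synthesize_composite(sources, cfg)

io.write_wav(out / "scene.wav", signal)
io.write_scene_sidecar(out / "scene.yaml", sources, cfg.rng_seed,
                       cfg.sample_rate, cfg.duration)

back = io.read_wav(out / "scene.wav")
doc = io.read_scene_sidecar(out / "scene.yaml")
print(f"wrote {out/'scene.wav'} ({back.duration:.1f} s at {back.sample_rate:.0f} Hz)")
print(f"sidecar sources: {[s.eod_frequency for s in doc['sources']]} Hz, "
      f"seed {doc['rng_seed']}")
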