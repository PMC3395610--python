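"""How single P-units and a population encode beats versus motion.

Simulates P-units on a moving two-fish scene and quantifies, via
magnitude-squared coherence and the Gaussian mutual-information rate, that
(i) spike trains carry the beat frequency even though the raw stimulus has
no power there, (ii) low-P-value units encode the slow motion envelope E2
better than high-P-value units, and (iii) averaging a small population
tracks E2 better than a high-P single unit.
"""

import numpy as np
from scipy.stats import pearsonr

import eodscene as es

EODF = 827.0
sources = [es.EODSourceSpec(EODF), es.EODSourceSpec(763.0, 0.143, 0.56)]
cfg = es.SignalConfig(duration=30.0, sample_rate=100_000.0, rng_seed=4)
signal, _ = es.synthesize_composite(sources, cfg)
pair = es.extract_envelopes(signal)

units = {
    p: es.calibrate_noise_for_pvalue(p, EODF, calibration_seed=10 + i)
    for i, p in enumerate((0.12, 0.40))
}
for i, (p, params) in enumerate(units.items()):
    train = es.simulate_punit(signal, params, seed=20 + i)
    rate = es.spike_rate_series(train)
    coh_e1 = es.coherence(pair.e1, rate, segment_seconds=2.0)
    coh_e2 = es.coherence(pair.e2, rate, segment_seconds=2.0)
    i_pk = np.argmax(np.where(coh_e1.frequencies >= 5.0, coh_e1.coherence, 0.0))
    mi = es.mutual_info_rate(coh_e2, 0.0, 20.0)
    print(f"P = {p:.2f}: E1 coherence peaks at {coh_e1.frequencies[i_pk]:.1f} Hz "
          f"(height {coh_e1.coherence[i_pk]:.2f}); "
          f"E2 coherence max (0-20 Hz) {coh_e2.band_max(0.5, 20):.2f}; "
          f"MI {mi.rate:.2f} bits/s")

pop = es.sample_population(n=30, eodf=EODF, master_seed=5)
pop_rate = es.population_rate(pop, signal, window=0.1)
e2_w = np.interp(pop_rate.times, pair.e2.times, pair.e2.samples)
print(f"30-unit population rate vs E2: r = {pearsonr(pop_rate.samples, e2_w).statistic:.2f}")
# Beats are a single-unit code; the slow motion envelope is best read from
# low-rate units or from the averaged population activity.
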