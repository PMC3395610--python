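# Methods

## The composite EOD scene

A wave-type electric fish emits a quasi-sinusoidal electric organ discharge
(EOD) at an individually fixed frequency (700–1100 Hz in brown ghost
knifefish). Near a "receiving" fish, the fields of `N` fish superpose; with
harmonics neglected the received signal is modelled as

    S(t) = Σₙ aₙ(t) · sin(2π fₙ t + φₙ),        n = 1 … N

where fish 1 is the receiver with amplitude fixed at `a₁ ≡ 1`. Each
neighbour's amplitude wanders as it swims:

    aₙ(t) = Aₙ (1 + σₙ ξₙ(t)),

with `Aₙ` the mean relative amplitude (∝ 1/distance), `σₙ` the relative
fluctuation scale, and `ξₙ` a zero-mean, unit-variance Ornstein–Uhlenbeck
process (OUP) with correlation time `τ_c`: low-pass Gaussian noise with
autocorrelation `exp(−|Δt|/τ_c)`. Phases default to 0 (they do not affect
envelope spectra). Instantaneous amplitudes are deliberately not clipped at
zero; envelope analysis sees the magnitude.

The OUP is discretized with the exact AR(1) update
`ξ_{k+1} = ξ_k e^{−Δt/τ_c} + √(1−e^{−2Δt/τ_c}) z_k`, `ξ_0 ~ N(0,1)`, so the
stationary unit variance holds at any step size (Euler–Maruyama would bias
it). Each fish draws from an independent child stream of the master seed
(fixed spawn keys), so adding a fish never perturbs the others'
realizations.

**Parameter conventions.** Two equivalent parameterizations of the
fluctuation exist: the relative scale `σₙ` above, and the absolute
amplitude SD `σ_abs = Aₙ σₙ`. Contrast statistics map onto them directly
(mean contrast ≈ `Aₙ`, SD of contrast ≈ `σ_abs`), and a measured pair of
contrast statistics converts via `EODSourceSpec.from_contrast`. Parameter
sweeps in the trend suite hold `σ_abs` fixed while sweeping `A₂` (and vice
versa): that is the convention under which the beat-peak width is
insensitive to `A₂` and the period jitter falls as the neighbour gets
closer; sweeping with the relative `σ₂` fixed instead couples jitter to
`A₂` and reverses the period-CV trend.

**Defaults.** Sample rate 100 kHz (matching the receptor model's 0.01 ms
step), with a 20 kHz fast mode for envelope-only analyses (all envelope
content is below a few hundred Hz). `τ_c` defaults to 0.5 s — a
configuration choice on the order of observed envelope decorrelation
times, not a fitted constant; it is exposed per fish. The representative
two-fish scene uses `A₂ = 0.143`, `σ₂ = 0.56` (i.e. contrast mean 0.143, SD
0.08); realistic ranges are mean contrast 0.07–0.20 and SD/mean 0.5–0.9.

SAM (`(1+M sin 2πf_m t)·carrier`) and narrowband RAM (carrier × `(1+m(t))`
with `m` hard-band-limited Gaussian noise scaled to a requested coefficient
of variation) are provided as laboratory mimic stimuli.

## Envelopes

* **E1 (first envelope, the AM):** magnitude of the analytic signal
  (Hilbert transform), then a zero-phase 4th-order Butterworth low-pass at
  200 Hz to remove the residual line at the EOD frequency. Zero-phase
  filtering preserves envelope timing for coherence analysis.
* **E2 (second envelope):** within each 0.1 s window of E1, the window mean
  is removed, the analytic-signal magnitude of the residual beat
  oscillation taken, and the mean added back; windows are assembled end to
  end and the result low-passed at 50 Hz to suppress boundary
  discontinuities. For static neighbours E2 is constant; with ≥3 fish it
  oscillates at the secondary beats; with swimming neighbours it tracks the
  summed neighbour amplitude (Pearson r > 0.95 at default parameters).
* **Direct envelope:** monotone piecewise-cubic (PCHIP) interpolation
  through successive local maxima, used as an independent cross-check
  (agrees with the analytic-signal envelope within 5% normalized RMS).

The first and last 50 ms of any envelope are excluded from statistics
(filter settling). Local extrema use a deterministic tie-break: plateaus
count once, at their left edge.

**Instantaneous contrast.** For each local maximum `H` of E1 and the
nearest following minimum `L`, contrast = `(H−L)/(H+L)`; the mean and SD
over all pairs are reported. For a weak neighbour the small-amplitude
expansion of the AM, `1 + A₂(1+σ₂ξ)cos(2πΔf t)`, predicts mean ≈ `A₂` and
SD ≈ `A₂σ₂`. Two known small biases: the folded Gaussian (|amplitude|)
shrinks the measured SD by ~5% at `σ₂ ≈ 0.56`, and finite records
undersample the slow OUP; both stay within the 10% tolerance used in the
tests at 60 s × 20 seeds.

## Spectral characterization

PSDs are Welch estimates (Hann, 2 s segments, 50% overlap by default) —
0.5 Hz resolution with ≥11 averages on a 12 s record. Parseval holds to a
few percent provided the segment resolves the signal's slowest power; an
OUP with `τ_c = 0.5` s keeps ~20% of its power below 0.1 Hz and therefore
needs ≳60 s segments for a faithful total.

Peak metrics: height is the maximum density near the nominal center, width
the distance between the two flanking crossings of an explicit reference
level (linear interpolation between grid points), resolution =
height/width. The reference level is a parameter because absolute density
levels depend on overall signal scaling: analyses that compare across a
sweep fix one level derived from the first sweep point (either ~10× the
spectral noise floor, or 10⁻³ of the first peak height, whichever is
larger) and hold it constant.

Autocorrelations are mean-removed, unbiased (lag-k sums divided by `N−k`)
and averaged over segments (default 15 s, suited to minutes-long records;
single-segment mode for shorter simulations — per-segment mean removal
depresses the ACF by ~2τ_c/T_segment, which matters at 15 s). The OUP
correlation time is recovered by least-squares fit of `exp(−Δt/τ)` over
lags with ACF > 0.05.

E1 periods are measured between successive upward crossings of the record
mean with sub-sample linear interpolation, histogrammed in 0.02 ms bins
anchored at zero; the mode is the center of the maximal bin (ties → lower
bin); CV = SD/mean.

## P-unit model

P-units are simulated as leaky integrate-and-fire neurons with a dynamic
threshold (LIFDT):

    dv/dt = −v/τ_v + g·H(s)·s + √(2D)·ζ(t)
    dθ/dt = −(θ − θ₀)/τ_θ ;   spike when v ≥ θ:  v → 0, θ → θ + Δθ

with `H` the Heaviside function (receptors rectify the field) and `ζ` white
noise. Euler–Maruyama integration at 0.01 ms; the noise term enters as
`√(2D·dt)·N(0,1)` per step. Defaults: `τ_v = 1` ms, `τ_θ = 10` ms,
`Δθ = 0.03`, `θ₀ = 1`, gain `g = 2200 s⁻¹`. These are package choices
(standard published LIFDT magnitudes for the time constants; gain set so
that the noise-free operating point is just subthreshold), selected once so
that the baseline P-value — firing rate ÷ EOD frequency — is a monotone
function of `D` spanning the physiological range 0.1–0.6 while keeping
vector strength > 0.3 at mid-range. They are not measurements, which is why
`D` is always calibrated rather than trusted.

**Calibration.** `calibrate_noise_for_pvalue` bisects `D` (geometric steps
over a 6-decade bracket) against a 20 s baseline simulation with a frozen
noise realization (one standard-normal array rescaled by √D), making the
map D → P deterministic; convergence is to ±0.01. The calibration seed is
derived from a dedicated spawn key so calibration never consumes analysis
randomness. `calibrate_gain_for_pvalue` is the complementary mode: all
units share one noise intensity and differ in drive gain. The two modes
embody different assumptions about why receptors differ: under noise
calibration, low-P units are the *least* noisy and hence the most
stimulus-locked; under gain calibration all units are equally noisy and
differences isolate the effect of firing rate. Slow-envelope coding
analyses use noise calibration (it reproduces the low-P advantage for
motion coding); the fast narrowband-RAM control uses gain calibration,
which is the regime in which faster-firing units track fast amplitude
modulations better — with noise calibration that ordering inverts, because
extra spikes come bundled with extra jitter.

**Population.** Target P-values are drawn from a log-normal (log-median
0.245, log-SD 0.35) truncated to [0.1, 0.6], giving a truncated mean of
≈0.26; each of the 200 units is calibrated independently and its realized
P-value re-measured on an independent 20 s baseline run.

## Coding metrics

Spike trains become rate series on a 0.5 ms grid (counts per bin ÷ bin);
envelopes are decimated to the same grid (their content is ≤200 Hz, far
below the 1 kHz Nyquist). Cross-spectra and magnitude-squared coherence use
the same Welch settings as the PSDs; single-segment coherence is refused
(identically 1), and the ~1/n_segments positive bias of coherence against
independent signals is kept below the 0.15 reference level used for
coherence peak widths. The mutual-information rate over a band is the
Gaussian-channel bound `−∫ log₂(1−C(f)) df` (trapezoidal on the native
grid, DC bin excluded, coherence capped at 1−10⁻⁶).

Coherence against stochastic spike trains uses single long records
(30–60 s); averaging over seeds is reserved for summary statistics.

## Problem sizes

Scene-level statistics use 12 s records (spectra), 60 s (contrast and
correlation-time recovery; 10–20 seeds), 120 s for the period-histogram
mode. Encoding analyses use 30–60 s records at 100 kHz. Trend sweeps run 5
points × 5 replicates with common random numbers across sweep values —
paired comparisons remove OUP-realization scatter that would otherwise
require ~50 replicates per point, which is the replicate count the full
pipeline defaults to (`run_parameter_sweep(..., replicates=50)`).

## What the generator does and does not emulate

It emulates: multi-fish superposition at constant EOD frequencies,
motion-induced amplitude fluctuation with a single correlation time, the
measured contrast ranges, and 100 kHz sampling. It does not emulate: EOD
harmonics (pure sinusoids only), chirps or other frequency excursions,
spatial field geometry (amplitude stands in for all distance/orientation
effects), phase modulation, self-motion of the receiver, or measurement
noise. Passing tests therefore validate the analysis chain on the model's
own terms; on real recordings the envelope extraction additionally faces
harmonics and nonstationary EOD frequencies, which the 200 Hz low-pass and
windowed E2 handle only for beats below ~200 Hz.

## Known limitations

* The receptor heterogeneity question (noise-dominated vs gain-dominated
  differences between low- and high-rate units) is left open; both
  calibration modes are provided and the choice changes which unit best
  encodes fast modulations (see above).
* Contrast SD carries the ~5% folded-Gaussian bias at large σ₂.
* Correlation-time fits from 15 s segments are biased low by per-segment
  mean removal; use longer segments for simulation-length records.
* The LIFDT is phenomenological: no conductances, no adaptation cascades,
  no efferent feedback; population units are statistically independent.
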