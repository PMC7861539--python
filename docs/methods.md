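# Methods

## Model

Each of the two populations is a Wendling-type CA1 neural mass: four
interacting subpopulations (pyramidal cells, excitatory interneurons as a
pyramidal self-feedback loop, slow dendrite-projecting interneurons, fast
soma-projecting interneurons) linked by the wave-to-pulse sigmoid
S(v) = 2e₀/(1 + e^{r(v₀−v)}) and second-order "pulse-to-wave" synaptic
filters with impulse response h(t) = G·w·t·e^{−wt}. In state-space form
every filter contributes a (PSP, PSP-velocity) pair, ten state variables
per population, twenty for the coupled system.

Populations are coupled bidirectionally and symmetrically: the partner's
excitatory PSP state y₁ʲ, delayed by τ_d, enters the pyramidal-cell
membrane potential scaled by K. The recorded LFP is that same membrane
potential, K·y₁ʲ(t−τ_d) + y₁ⁱ − y₂ⁱ − y₃ⁱ — the potential that actually
drives pyramidal firing. A config switch (`lfp_includes_coupling=False`)
drops the coupling term for users who prefer the purely local PSP balance.

Default parameters (units): A = 4.0 mV, B = 40 mV, G = 20 mV;
a = 100 s⁻¹, b = 50 s⁻¹, g = 350 s⁻¹; C1 = 135, C2 = 0.8·C1,
C3 = C4 = 0.25·C1, C5 = C6 = 0.1·C1, C7 = 0.8·C1; v₀ = 6 mV,
e₀ = 2.5 s⁻¹, r = 0.56 mV⁻¹; K = 0.3, τ_d = 10 ms; input noise
p ~ N(90, 1.3) APs/s per population, independent streams.

## Integration

Explicit Euler–Maruyama on a fixed grid, dt = 1.95 ms (512 Hz). The delay
is handled by reading the partner's recorded y₁ trajectory
round(τ_d/dt) = 5 steps back (zeros before the delay horizon; no
interpolation). Initial conditions are the zero state, so every run opens
with a brief (<1 s) transient before settling into its regime; epoch
extraction starts at 2 s, after the transient.

Noise convention: one N(μ, σ) pulse-density value is drawn per step and
held constant over the step. This treats p(t) as a sampled input signal —
the convention of this model lineage — and makes the effective noise power
dt-dependent; dt is fixed by default so this is immaterial in practice.
`noise_mode="sqrt_dt"` instead scales fluctuations by 1/√dt, recovering
the formal SDE diffusion scaling (equivalent to a continuous noise SD of
1.3/√dt ≈ 29 APs/s at the default step, close to the classic value used
with this model family). Per-sample is the default.

Numerical guards: a UserWarning when dt ≥ 2/g (the explicit-Euler
stability bound of the fastest filter), and an `IntegrationDivergedError`
naming the step if the state leaves the finite range. The scheme is
order 1: halving dt changes a noise-free default trajectory by < 0.5% RMS.

## Dynamical regimes

With the printed coupling (K·y₁ʲ inside the pyramidal sigmoid), the
partner's y₁ carries the full external-input drive (~5 mV at rest), so
K = 0.3 contributes ≈ 1.5 mV of standing depolarization. Consequences,
mapped numerically with the noise-free system:

- defaults (A = 4, B = 40, G = 20, K = 0.3): stable fixed point,
  LFP ≈ 0.87 mV, background fluctuations well below the 5 mV spike
  threshold;
- the sustained-discharge threshold of the coupled system sits near
  A₁ ≈ 4.25 (B₁ ≈ 35 when ramping inhibition down, K ≈ 0.4 when ramping
  coupling up), so each standard ramp (A₁ 2.5→4.6, B₁ 45→30, K 0→0.5)
  crosses into spiking late in the run;
- A₁ = 5.0 produces an immediate, robust sustained discharge
  (LFP peaks ≈ 14 mV).

Because the pro-ictal A-window (A₁ 4.30→4.95) therefore starts essentially
at threshold, onset latencies in that experiment are short and nearly
amplitude-independent; the safety conclusion (no Tukey-significant
difference between probed and passive onset latencies) is unaffected.

## Protocol and settings

Probing pulses are rectangular boxcars in pulse-density units: width
10 ms, period 2 s, amplitude E_stim ∈ [0, 200] APs/s, first pulse at 2 s.
Parameter ramps are linear over a configurable window (default the whole
run) and clamped outside it. Named settings pair a ramp with a
stimulation laterality: I-A/I-B/I-K probe population 2 while population 1
(or the coupling) becomes ictogenic; II-A/II-B/II-K probe both
populations; S-A/S-B probe the ictogenic population 1 itself. For the
pro-ictal experiment the registered window for the A-ramp is 4.30→4.95;
the B and K extensions (45→25 and 0→0.8) are package choices, verified to
cross the discharge threshold, and configurable.

## Features

Epochs are the 400 ms (205-sample) windows starting at each pulse-onset
grid sample; passive runs use the same virtual schedule so probed and
passive series align one-to-one. Per epoch and population: variance
(1/n normalization), skewness m₃/m₂^{3/2}, kurtosis m₄/m₂² (Pearson —
a Gaussian scores 3; rank correlations are unaffected by the −3 shift),
lag-1 autocorrelation, and between populations the plug-in histogram
mutual information with 16 equal-width bins per epoch range (≈ √205,
rounded to a power of two), in bits. Zero-variance epochs yield missing
standardized moments and zero MI. Each feature series is smoothed with a
causal order-20 moving average (mean of the last 20 available values,
shorter prefixes averaged as-is, missing values skipped); causal
alignment suits forecasting, a centered variant is available.

## Scoring and statistics

Forecasting power is Spearman's ρ between the smoothed feature series and
the ramp evaluated at epoch onsets (ties get average ranks); smoothed
series are the default correlation input. The amplitude sweep repeats
this over a grid (0 to 200 APs/s, step 20, by default) with 15
realizations per amplitude; each (amplitude, realization) cell derives
its own CRC-based seed from the base seed, so no noise stream is shared
across cells and the entire sweep is reproducible from one integer.
Tukey's HSD (Tukey–Kramer for unequal groups) compares each amplitude's
ρ distribution against the passive group at α = 0.05, applied directly to
the ρ values. Spike detection: local maxima above 5 mV separated by at
least 100 ms, with peaks within 200 ms after any pulse onset discarded.
Ictal onset: the first run of 5 spikes whose successive gaps are all
≤ 4 s (a literal ≥ reading is available via `isi_mode="min"`); the
pro-ictal experiment reports per-realization latencies, a one-way ANOVA
across amplitudes, and Tukey HSD versus passive.

## What the simulations do and do not show

The generator produces the study conditions themselves — there is no
external data. Passing tests therefore demonstrate internal consistency
of the model, estimators and statistics under Gaussian input noise and
linear parameter drift; they do not establish that probing features
forecast seizures in real EEG, where noise is non-Gaussian and
nonstationary, drifts are not monotone, and electrode and volume-conduction
effects intervene. Reduced problem sizes are used for the bundled
end-to-end checks (400 s runs with 5 realizations for the sweep ordering;
2000 s runs with 10 realizations for the pro-ictal null), chosen as the
smallest sizes at which the qualitative orderings are stable across seeds.

## Known limitations

- Two populations only; no network topologies or plastic coupling.
- Rectangular pulse-density stimuli; no biphasic/charge-balanced shaping,
  no closed-loop stimulation.
- The plug-in MI estimator is positively biased at small epoch lengths
  (bounded by (bins−1)²/(2·n·ln 2)); comparisons across conditions use
  equal epoch sizes, so the bias largely cancels.
- Only the normal-background and sustained-discharge regimes are
  operationalized; the model's other activity classes (sporadic spikes,
  rhythmic, low-voltage fast, quasi-sinusoidal) are not classified.
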