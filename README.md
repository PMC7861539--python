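# nmprobe

Seizure forecasting by **active probing** in a coupled neural mass model.

Epileptic seizures are preceded by slow, hidden changes in cortical
excitability that passive EEG monitoring often fails to expose. One
proposed remedy is *active probing*: deliver weak, low-frequency electrical
stimuli and watch how the evoked responses change as the brain drifts
toward a seizure — a strategy rooted in the theory of critical slowing
down near dynamical tipping points. `nmprobe` provides a complete in
silico test bed for this idea, aimed at computational neuroscientists and
neural-engineering researchers studying seizure-prediction and
neurostimulation paradigms.

## The model

Two Wendling-type neural mass models of the hippocampal CA1 circuit — each
lumping pyramidal cells, excitatory interneurons, slow dendritic
inhibition (gain *B*) and fast somatic inhibition (gain *G*) — are coupled
bidirectionally through their pyramidal cells with gain *K* and a 10 ms
conduction delay, mimicking inter-hemispheric coupling. Each population
obeys ten stochastic differential equations built from two primitives:

- the wave-to-pulse sigmoid *S(v) = 2e₀ / (1 + e^{r(v₀−v)})*, converting
  mean membrane potential to firing density, and
- second-order synaptic filters with impulse response
  *h(t) = G·w·t·e^{−wt}* converting firing density to post-synaptic
  potential.

The simulated LFP of population *i* is the pyramidal membrane potential
*K·y₁ʲ(t−τ_d) + y₁ⁱ − y₂ⁱ − y₃ⁱ*. The system is integrated with the
Euler–Maruyama scheme at 512 Hz (step 1.95 ms), driven by Gaussian input
noise *p(t) ~ N(90, 1.3)* APs/s.

A seizure-like transition is induced by linearly ramping one parameter
over the run — pyramidal gain *A₁* up, slow inhibition *B₁* down, or
coupling *K* up — while a probing train (10 ms pulses, amplitude
*E_stim* APs/s, every 2 s) stimulates one or both populations. From each
400 ms post-stimulus epoch the pipeline extracts variance, skewness,
kurtosis, lag-1 autocorrelation and inter-population mutual information,
smooths each series with an order-20 moving average, and scores
forecasting power as the Spearman rank correlation ρ between the feature
series and the ramped parameter. An amplitude sweep with Tukey-HSD
comparisons against passive observation (amplitude 0) quantifies what
probing adds; a pro-ictal safety experiment checks that probing does not
itself hasten seizure onset.

## Worked example

Probing both populations while the coupling gain ramps from 0 to 0.5
(setting II-K, reduced to 400 s runs with 5 realizations per amplitude):

```python
import nmprobe as nm

setting = nm.build_setting("II-K", t_end=400.0)
sweep = nm.run_amplitude_sweep(setting, amplitudes=[0, 120], n_realizations=5,
                               base_seed=1, duration=400.0)
summary = (sweep.correlations
           .groupby(["feature", "population", "amplitude"]).rho.mean()
           .unstack().round(3))
print(summary)
```

```text
amplitude                        0      120
feature            population
kurtosis           1           0.439 -0.943
                   2           0.397 -0.944
lag1_ac            1           0.704  0.763
                   2           0.726  0.761
mutual_information 0           0.897  0.983
skewness           1           0.462 -0.931
                   2           0.294 -0.931
variance           1           0.872  0.992
                   2           0.840  0.991
```

Each entry is the mean Spearman ρ between a smoothed feature series and
the coupling gain *K* (population 0 denotes the pairwise
mutual-information feature). With 120 APs/s probing, the variance of
either stimulated population tracks the rising coupling almost perfectly
(ρ ≈ 0.99 vs ≈ 0.86 passively), mutual information sharpens
(0.90 → 0.98), and skewness/kurtosis flip into strong *negative*
correlates as evoked responses become stereotyped — probing turns a
mediocre passive forecast into a near-perfect one. `sweep.significance`
reports which amplitudes differ significantly from passive observation
(for variance here, adjusted p < 0.002 in both populations).

The same pipeline is scriptable from the shell:

```bash
nmprobe sweep --setting II-K --duration 400 --amplitudes 0,120 \
        --n-realizations 5 --seed 1 --out results/iik
nmprobe report results/iik
nmprobe proictal --setting II-A --amplitudes 0,120 --seed 1 --out results/safety
```

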