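# spikelesion

Simulation and analysis of **neurodegeneration in spiking cortical
microcircuits**: how progressive neuron loss reshapes population activity and
rhythmic oscillations, and how spike-timing-dependent plasticity (STDP)
restructures the surviving synapses afterwards.

The package is aimed at computational neuroscientists studying network-level
consequences of injury (e.g. traumatic brain injury at the microcircuit
scale). It provides, as an importable library:

- **Network generation** — Erdős–Rényi-style random directed networks of
  Izhikevich neurons placed on a unit sphere: 80 % regular-spiking excitatory
  (a=0.02, b=0.2, c=−65, d=8) and 20 % fast-spiking inhibitory (a=0.1, b=0.2,
  c=−65, d=2) with per-neuron parameter jitter, ~100 connections per neuron,
  bimodally seeded excitatory weights on [0, 4], normal inhibitory weights on
  [−14, 0], and transmission delays proportional to arclength, capped at 8 ms.
- **Dynamics** — forward-Euler integration (Δt = 0.2 ms) of

  v′ = 0.04 v² + 5 v + 140 − u + I,  u′ = a(bv − u),
  with reset v ← c, u ← u + d when v ≥ 30 mV,

  exponentially decaying synaptic currents (τ = 5 ms), post-spike input
  desensitization (to 60 %, recovering with τ = 150 ms), and per-neuron
  Poisson background events (1 Hz) with gamma-distributed amplitudes
  (k = 2, θ = ½).
- **Plasticity** — additive Song-model STDP at excitatory→excitatory synapses
  (τ = 20 ms, Δw = ±A e^(−|Δt|/τ), hard bounds [0, 4]), implemented online
  with eligibility traces that are provably equivalent to all-pairs summation.
- **Injury** — random deletion preserving the 4:1 E/I ratio, focal
  (spatially contiguous) lesions, and activity-ranked deletion of the lowest-
  (LFR) or highest- (HFR) firing excitatory neurons.
- **Metrics** — firing rate, CoV of inter-spike intervals, and oscillation
  frequency / peak magnitude / FWHM from prominence-qualified peaks of a
  10-ms sliding spike count; within-oscillation phase occupancy; the
  neuron-connectivity index (Σ|w_in| − Σ|w_out|)/(Σ|w_in| + Σ|w_out|).
- **Experiment orchestration** — settle → measure → injure → measure →
  recover protocols across injury grids and E/I compositions, with one-way
  ANOVA + Tukey–Kramer and Bonferroni-corrected Welch t-tests.

## Worked example

`examples/injure_and_recover.py` settles a reduced 300-neuron network (same
per-neuron connectivity statistics as the 1000-neuron default), deletes half
of it at random, and lets STDP rebalance the survivors:

```
deleted 150 of 300 neurons (120 excitatory)
phase             rate Hz   osc /s   peak %
baseline             5.52     25.1     13.1
post-injury          2.41     20.1      6.3
post-plasticity      2.78     20.0      7.3
```

The lesion halves population activity and weakens oscillations (fewer events,
smaller peak fraction of the network recruited); a subsequent plasticity
period recovers part of the firing-rate deficit. The other examples each
exercise one capability: `build_network.py` (structure), `simulate_baseline.py`
(settling and the five metrics), `targeted_deletion.py` (LFR vs HFR deletion —
removing *inactive* neurons cuts activity more than removing the most active
ones), `oscillation_anatomy.py` (phase occupancy: inhibitory firing lags the
oscillation peak; excitatory index–rate correlation r ≈ 0.88), and
`ei_balance_sweep.py` (excitatory fraction vs baseline dynamics).

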