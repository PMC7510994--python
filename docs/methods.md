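# Methods

## Model overview

`spikelesion` simulates isolated cortical microcircuits as networks of
Izhikevich two-variable quadratic integrate-and-fire neurons. Each neuron
follows

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

integrated with forward Euler at a fixed Δt = 0.2 ms. Excitatory neurons are
parameterized as regular-spiking (a=0.02, b=0.2, c=−65, d=8), inhibitory
neurons as fast-spiking (a=0.1, b=0.2, c=−65, d=2); each parameter is
independently jittered by ±5 % (uniform) per neuron so the population is
heterogeneous. The jitter fraction is configurable and zero-jitter mode is
retained for deterministic tests.

The total input current of a neuron at a step is `I = g_exc + g_inh + I_bg`:
two current-like accumulators (no reversal potentials) decaying by
`exp(-Δt/τ)` with τ = 5 ms (AMPA / GABA_A-like kinetics; slow NMDA / GABA_B
currents are out of scope), plus the background injection for that step.

## Network substrate

Neurons are placed uniformly on the unit sphere (normalized Gaussian
triples). Each neuron draws a target out-degree from Normal(mean_degree/2,
(0.1 · mean_degree/2)²), rounded and clipped to [1, n−1], and connects to
uniformly chosen non-self targets without replacement — in-degree then
arises from random targeting, so total degree averages `mean_degree`
(default 100). The "10 % variance" of the degree and inhibitory-weight
distributions is interpreted as a 10 % coefficient of variation of the
seeding scale, and the 100-connection figure as *total* (in + out) degree;
both readings are configurable.

Excitatory weights are seeded from an equal-mass two-lobe mixture
(Beta(2, 8) and its mirror) on [0, 1], scaled to [0, 4] — a bimodal seed
chosen because additive STDP drives weights toward the bounds, so seeding
near the plasticity fixed point shortens settling. Inhibitory weights draw
from Normal(0.5, 0.05) on [0, 1], clipped, and map linearly onto [−14, 0].
Delays are `8 ms × arclength/π`, rounded *up* to the Δt grid with a one-step
floor (a zero delay would break event ordering); self-edges and duplicate
edges are excluded. Only the random (Erdős–Rényi-like) topology is
implemented; distance-dependent variants are out of scope.

## Background drive

Each neuron receives an independent 1 Hz Poisson stream of current events
with amplitude `gain × Gamma(k=2, θ=0.5)` (unit mean before gain). The
default gain of 15 deposits the event on the decaying excitatory accumulator,
which makes the mean-amplitude event reliably fire a resting regular-spiking
neuron (a one-timestep impulse of the same size cannot, because a 0.2-ms
pulse of ~15 pA-equivalent does not clear the unstable fixed point; the
impulse variant is available as `StimulusModel(mode="impulse")`). At gain 15
roughly three quarters of gamma draws fire a resting neuron; raising the
gain until nearly every event fires (>0.95) would require gain ≈ 45 and
drives the network far above the intended activity regime, so the gain is
left at 15.

## Desensitization

Immediately after a neuron spikes, its *incoming* synaptic efficacy is
attenuated to 60 % (factor 0.6, reset non-cumulatively on each spike) and
relaxes back toward 1 with τ = 150 ms. "Attenuated at 40 %" is read as
attenuated *by* 40 %; the alternative (to 40 %, i.e. floor 0.4) is a config
switch and produces the same qualitative regime.

## Plasticity

STDP applies to excitatory→excitatory synapses only (inhibitory plasticity
is deliberately out of scope). The rule is the additive Song model:

    Δw = +A+ exp(-Δt/τ)   if Δt = t_post − t_pre > 0
    Δw = −A− exp(+Δt/τ)   if Δt ≤ 0        (coincidence depresses)

with τ = 20 ms, A+ = 0.005·w_max = 0.02, A− = 1.05·A+ (slight depression
dominance), and hard clipping to [0, 4]. Updates are all-pairs, implemented
online with exponentially decaying pre/post traces; the test suite proves
trace/all-pairs equivalence to 1e−9 on random trains. Pairing uses spike
*emission* times by default; an arrival-time variant (pre spike shifted by
the axonal delay, with per-edge lazily decayed traces) is selectable via
`STDPConfig(timing="arrival")`. Within a timestep, simultaneous pre/post
spikes fall on the depression branch, and potentiation is strictly causal.
Under this rule the E→E weight distribution migrates toward the bounds; the
suite asserts that the mass in the middle half of the range at least halves
after 30 simulated minutes on a 200-neuron network.

## Settling and protocols

A network "settles" by simulating with STDP in 5-minute blocks until both
the mean firing rate and the oscillation frequency change by < 1 % (relative)
between consecutive blocks, capped at 4 h simulated time (a warning is
recorded at the cap and the run proceeds). Injury protocols then copy the
settled network, delete neurons (fractions are of the *original* size,
applied once per level, not cumulatively), measure 5 minutes with frozen
weights, let STDP restructure under the same convergence rule (4 h cap), and
measure again. One master seed spawns per-replicate and per-stage child
streams, so all conditions within a replicate share the same settled network
and the whole protocol is bit-reproducible. When a lesion is applied, the
surviving neurons' membrane state carries over and the in-flight spike queue
is purged (at most 8 ms of drive, negligible against 5-minute windows).
LFR/HFR deletion ranks excitatory neurons by their rates over the final
pre-injury window; focal lesions remove the k nearest neurons to a random
center regardless of kind.

## Metrics

- **Firing rate**: spikes per neuron over the window (silent survivors count
  as 0), averaged over all survivors.
- **CoV ISI**: SD/mean of inter-spike intervals per neuron (≥ 2 spikes),
  averaged over qualifying neurons.
- **Oscillations**: the spike count in a 10-ms window sliding at Δt is
  scanned for local maxima with topographic prominence above threshold and
  ≥ 10 ms separation (preventing double-counts of one volley). FWHM is the
  interpolated width at half the prominence-referenced height — absolute
  half-height is undefined when background activity exceeds half the peak.
  Magnitude is the peak count, also reported as a fraction of the surviving
  network. Frequency is events per second; windows without detected events
  record the oscillation metrics as missing, not zero.
- **Prominence units**: the acceptance threshold defaults to 1 % of the
  surviving network (10 spikes at n = 1000) rather than an absolute 1 spike.
  With a 1-spike threshold the detector saturates near the 10-ms-separation
  ceiling (~70–100 "peaks"/s) because ordinary Poisson ripples of the count
  trace qualify, which degenerates the metric; the relative threshold yields
  discrete population events in the physiological range. Absolute-spike mode
  remains available. Within injury experiments the threshold is additionally
  *pinned* to the intact network size (`pinned_metrics`), so post-injury
  windows are measured with the same detector as their baseline; otherwise
  the shrinking threshold tracks the survivor count into the noise floor and
  reverses the apparent direction of the oscillation-frequency change.
- **Phase occupancy**: spikes inside each oscillation interval (1.4 × FWHM
  centered on the peak) are binned into deciles or quintiles per neuron
  group and normalized to the group's in-interval total ("likelihood to
  fire" is the group's spike fraction per bin, not a per-neuron
  probability).
- **Connectivity index**: (Σ|w_in| − Σ|w_out|)/(Σ|w_in| + Σ|w_out|) with
  absolute strengths, in [−1, 1]; undefined (NaN) for isolated neurons. Its
  Pearson correlation with firing rate is evaluated over excitatory neurons,
  whose synapses are the plastic ones; including non-plastic inhibitory
  neurons dilutes the relation.

## Reduced-scale profile

`desk_scale()` shrinks the network to n = 300 while keeping the mean degree
at 100, so every neuron retains the full-scale synaptic input statistics;
scaling the degree down proportionally instead collapses the model into a
background-driven regime without discrete population events. Settling and
recovery caps shrink to tens of simulated minutes. The reduced profile
preserves the qualitative regime (irregular firing at a few Hz, discrete
oscillations, strong excitatory index–rate correlation) and is what the test
suite exercises; absolute metric values at full scale differ quantitatively
(the synaptic "calibration to in-vivo potentials" underlying the reference
regime is not fully specified, and the package's baseline settles somewhat
hotter and more irregularly detectable than the reference one — see the
acceptance suite, where the full-scale baseline check documents this gap).

## Numerical and degenerate-input choices

- Threshold reset is applied within the step that crosses 30 mV; membrane
  state is always < 30 mV after a step, and a NaN/∞ membrane aborts with the
  neuron id and time.
- The delay calendar is a circular array of linked event lists with node
  recycling: O(1) amortized per spike event, bounded by in-flight events;
  the buffer grows (with state rollback) if a burst overflows it.
- Background events are pre-drawn outside the compiled kernel, so a run is
  bit-reproducible given (topology, seeds, config) and chunking does not
  affect results.
- Rate ties in LFR/HFR ranking break by a seeded shuffle; coincident neuron
  positions get the one-step minimum delay; zero-width oscillation events
  are skipped in phase occupancy; empty measurement windows raise.

## What the synthetic networks do and do not show

The generator emulates the stated structural conditions (sizes, composition,
degrees, weight scales, delays) but not anatomically realistic topologies,
conductance-based synapses, slow receptor kinetics, or region-specific cell
types. Passing tests therefore demonstrate the internal consistency of the
model and the direction of injury/plasticity effects under these idealized
conditions — not quantitative predictions for any specific brain region.
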