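"""Configuration dataclasses for network construction, dynamics, plasticity and protocols.

All times are in milliseconds unless a field name says otherwise; rates are in Hz.
Defaults reproduce the baseline cortical-microcircuit conditions: 1000 neurons,
80 % regular-spiking excitatory / 20 % fast-spiking inhibitory, ~100 connections
per neuron, excitatory weights on [0, 4], inhibitory on [-14, 0], delays up to
8 ms, forward-Euler integration at 0.2 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class NetworkConfig:
    """Structural parameters of the synthetic cortical microcircuit.

    ``mean_degree`` is the target mean *total* degree (inputs plus outputs);
    per-neuron out-degree is drawn from Normal(mean_degree/2,
    (degree_cv * mean_degree/2)^2) so that in + out averages ``mean_degree``.
    ``param_jitter`` is the fractional half-width of the uniform jitter applied
    to each Izhikevich parameter around its canonical phenotype value.
    """

    n: int = 1000
    frac_exc: float = 0.80
    mean_degree: float = 100.0
    degree_cv: float = 0.10
    exc_scale: tuple[float, float] = (0.0, 4.0)
    inh_scale: tuple[float, float] = (-14.0, 0.0)
    max_delay_ms: float = 8.0
    dt_ms: float = 0.2
    param_jitter: float = 0.05
    # shape of each lobe of the bimodal excitatory seed distribution on [0, 1]
    # (Beta(a, b) near 0, mirrored Beta(b, a) near 1, equal mass)
    bimodal_beta: tuple[float, float] = (2.0, 8.0)
    inh_seed_sigma: float = 0.05
    topology_mode: str = "random"  # only "random" is implemented


@dataclass(frozen=True)
class StimulusModel:
    """Stochastic background drive: per-neuron Poisson events with gamma amplitudes.

    Each neuron independently receives events at ``rate_hz``; the injected
    current is ``amplitude_gain`` times a Gamma(k, theta) draw (mean k*theta = 1
    with the defaults).  With ``mode="decay"`` the event deposits onto the
    exponentially decaying excitatory drive (so a single default-gain event
    reliably fires a resting regular-spiking neuron); ``mode="impulse"``
    injects the current for exactly one timestep instead.
    """

    rate_hz: float = 1.0
    k: float = 2.0
    theta: float = 0.5
    amplitude_gain: float = 15.0
    mode: str = "decay"

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("stimulus rate must be >= 0")
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.mode not in ("decay", "impulse"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")


@dataclass(frozen=True)
class SimConfig:
    """Integration and synapse parameters for the fixed-step simulator."""

    dt_ms: float = 0.2
    tau_syn_ms: float = 5.0       # AMPA / GABA_A exponential decay constant
    desens_floor: float = 0.6     # input gain immediately after a neuron's own spike
    desens_tau_ms: float = 150.0  # recovery of the desensitization factor toward 1
    spike_threshold_mv: float = 30.0


@dataclass(frozen=True)
class STDPConfig:
    """Additive (Song-model) spike-timing-dependent plasticity at E->E synapses.

    ``a_plus`` is the potentiation increment expressed as a fraction of
    ``w_max``; depression is ``a_minus_ratio`` times larger, giving the slight
    depression dominance that drives weights to a bimodal fixed point.
    ``timing`` selects whether pre-synaptic spike times are taken at emission
    (soma) or after the axonal delay (arrival at the synapse).
    """

    tau_ms: float = 20.0
    a_plus_frac: float = 0.005
    a_minus_ratio: float = 1.05
    w_max: float = 4.0
    w_min: float = 0.0
    timing: str = "emission"

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("STDP time constant must be > 0")
        if self.a_plus_frac <= 0 or self.a_minus_ratio <= 0:
            raise ValueError("STDP increments must be > 0")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.timing not in ("emission", "arrival"):
            raise ValueError(f"unknown STDP timing {self.timing!r}")

    @property
    def a_plus(self) -> float:
        return self.a_plus_frac * self.w_max

    @property
    def a_minus(self) -> float:
        return self.a_minus_ratio * self.a_plus


@dataclass(frozen=True)
class MetricsConfig:
    """Windowing and peak-detection parameters for the activity metrics."""

    count_window_ms: float = 10.0
    stride_ms: float = 0.2
    # Peak-acceptance prominence.  "fraction" scales the threshold with the
    # surviving network size (prominence_frac * n, i.e. 10 spikes for n=1000),
    # which keeps the detector selective for population events; "spikes" uses
    # the absolute prominence_min regardless of network size.
    prominence_mode: str = "fraction"
    prominence_frac: float = 0.01
    prominence_min: float = 1.0       # spikes per counting window ("spikes" mode)
    min_separation_ms: float = 10.0   # minimum spacing between accepted peaks
    interval_factor: float = 1.4      # oscillation interval = factor * FWHM around peak


@dataclass(frozen=True)
class ProtocolConfig:
    """Settle -> measure -> injure -> measure -> recover protocol parameters.

    The full-scale profile matches the baseline study conditions (1000 neurons,
    4 h settling cap, 10 replicates, 5-minute measurement windows).  Use
    :func:`desk_scale` for a reduced profile suitable for interactive runs.
    """

    network: NetworkConfig = field(default_factory=NetworkConfig)
    stimulus: StimulusModel = field(default_factory=StimulusModel)
    sim: SimConfig = field(default_factory=SimConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    n_replicates: int = 10
    settle_max_min: float = 240.0
    settle_tol: float = 0.01
    settle_window_min: float = 5.0
    measure_window_min: float = 5.0
    recovery_max_min: float = 240.0
    injury_fractions: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 20))
    injury_modes: tuple[str, ...] = ("random",)
    frac_exc_grid: tuple[float, ...] = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95)


def desk_scale(
    n: int = 300,
    settle_max_min: float = 20.0,
    recovery_max_min: float = 10.0,
    n_replicates: int = 5,
    **overrides,
) -> ProtocolConfig:
    """Reduced-scale protocol profile for interactive exploration and smoke runs.

    Only the neuron count shrinks; the mean degree stays at the full-scale 100
    so every neuron keeps the same synaptic input statistics (count times
    weight), which preserves the oscillatory regime and the structure-function
    relation of the full-scale network.  Scaling the degree down with ``n``
    instead collapses the network into a background-driven regime with no
    discrete population events.  Settling and recovery caps are shortened;
    measurement windows keep the 5-minute default.
    """

    base = ProtocolConfig()
    net = replace(base.network, n=n, mean_degree=base.network.mean_degree)
    return replace(
        base,
        network=net,
        n_replicates=n_replicates,
        settle_max_min=settle_max_min,
        recovery_max_min=recovery_max_min,
        **overrides,
    )
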