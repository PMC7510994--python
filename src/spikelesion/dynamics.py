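"""Fixed-timestep simulation of Izhikevich networks with delayed synapses,
post-spike input desensitization, and stochastic background drive.

The scalar operations (:func:`izhikevich_step`, :func:`decay_synapses`,
:func:`deliver_spike`, :func:`update_desensitization`) define the per-step
semantics in plain numpy; :func:`run_simulation` executes the same rules for a
whole network through the compiled kernel in :mod:`spikelesion._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernel
from .config import STDPConfig, SimConfig, StimulusModel
from .netgen import EXC, NetworkTopology


class NumericStateError(RuntimeError):
    """The membrane potential of a neuron diverged (NaN/inf) during integration."""

    def __init__(self, neuron_id: int, t_ms: float):
        self.neuron_id = neuron_id
        self.t_ms = t_ms
        super().__init__(f"non-finite membrane potential for neuron {neuron_id} at t={t_ms:.1f} ms")


@dataclass
class SpikeRaster:
    """Event log of a simulation window: (neuron id, spike time) pairs.

    ``neuron_ids`` lists every neuron alive during the window (silent ones
    included), so rate averages can count zeros.  Times are relative to the
    start of the window and strictly below ``duration_ms``.
    """

    times_ms: np.ndarray     # (k,) float64, nondecreasing
    ids: np.ndarray          # (k,) int64, original neuron ids
    duration_ms: float
    neuron_ids: np.ndarray   # (n,) int64, all surviving neuron ids

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)


@dataclass
class SimState:
    """Mutable per-neuron dynamical state plus the in-flight spike calendar."""

    v: np.ndarray
    u: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    s: np.ndarray
    x_trace: np.ndarray      # pre-synaptic STDP trace (emission timing)
    y_trace: np.ndarray      # post-synaptic STDP trace
    step: int = 0            # absolute step count since state creation
    # delay calendar (linked lists over recycled nodes)
    head: np.ndarray = field(default=None)
    node_edge: np.ndarray = field(default=None)
    node_next: np.ndarray = field(default=None)
    free_stack: np.ndarray = field(default=None)
    qstate: np.ndarray = field(default=None)
    # per-edge arrival traces (allocated lazily for arrival-timing STDP)
    etrace: np.ndarray = field(default=None)
    etrace_step: np.ndarray = field(default=None)
    arr_cnt: np.ndarray = field(default=None)
    arr_step: np.ndarray = field(default=None)

    @property
    def t_ms(self) -> float:
        return self.step * self._dt_ms

    _dt_ms: float = 0.2


def init_state(topology: NetworkTopology, sim: SimConfig = SimConfig(),
               queue_capacity: int | None = None) -> SimState:
    """Fresh resting state for ``topology``: v = c, u = b*v, empty queue."""
    n = topology.n_neurons
    m = topology.n_edges
    v = topology.c.copy()
    u = topology.b * v
    n_slots = int(round(topology.meta.get("max_delay_ms", 8.0) / sim.dt_ms)) + 1
    if queue_capacity is None:
        queue_capacity = max(4 * m, 1024)
    state = SimState(
        v=v, u=u,
        g_exc=np.zeros(n), g_inh=np.zeros(n), s=np.ones(n),
        x_trace=np.zeros(n), y_trace=np.zeros(n),
        step=0,
        head=np.full(n_slots, -1, dtype=np.int64),
        node_edge=np.zeros(queue_capacity, dtype=np.int64),
        node_next=np.full(queue_capacity, -1, dtype=np.int64),
        free_stack=np.arange(queue_capacity, dtype=np.int64),
        qstate=np.array([queue_capacity - 1], dtype=np.int64),
        etrace=np.zeros(0), etrace_step=np.zeros(0, dtype=np.int64),
        arr_cnt=np.zeros(0, dtype=np.int64), arr_step=np.full(0, -1, dtype=np.int64),
        _dt_ms=sim.dt_ms,
    )
    return state


# ---------------------------------------------------------------------------
# scalar reference operations


def izhikevich_step(v, u, current, a, b, c, d, dt=0.2, v_thresh=30.0):
    """One forward-Euler step of the two-variable quadratic neuron model.

    ``v' = v + dt (0.04 v^2 + 5 v + 140 - u + I)``,
    ``u' = u + dt a (b v - u)``; if ``v'`` crosses threshold the spike is
    recorded and the state resets (``v := c``, ``u := u' + d``).

    Returns ``(v', u', spiked)``.
    """
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u)) and np.all(np.isfinite(current))):
        raise NumericStateError(-1, float("nan"))
    vn = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    un = u + dt * a * (b * v - u)
    spiked = vn >= v_thresh
    vn = np.where(spiked, c, vn)
    un = np.where(spiked, un + d, un)
    if np.ndim(spiked) == 0:
        return float(vn), float(un), bool(spiked)
    return vn, un, spiked


def decay_synapses(g_exc, g_inh, dt=0.2, tau=5.0):
    """Exponential decay of the synaptic drive accumulators (AMPA / GABA_A)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    f = math.exp(-dt / tau)
    return g_exc * f, g_inh * f


def deliver_spike(g_exc, g_inh, post, weight, s_post):
    """Add a delivered spike to the target's drive, scaled by its desensitization."""
    if weight > 0:
        g_exc[post] += s_post * weight
    else:
        g_inh[post] += s_post * weight
    return g_exc, g_inh


def update_desensitization(s, spiked, dt=0.2, tau_d=150.0, floor=0.6):
    """Post-spike attenuation of a neuron's input gain, relaxing back toward 1."""
    if spiked:
        return floor
    return 1.0 - (1.0 - s) * math.exp(-dt / tau_d)


# ---------------------------------------------------------------------------
# background drive


def background_events(n_neurons: int, duration_ms: float, stim: StimulusModel = StimulusModel(),
                      seed=None):
    """Draw the stochastic background events for a window.

    Each neuron receives an independent homogeneous Poisson stream at
    ``stim.rate_hz``; amplitudes are ``stim.amplitude_gain`` times Gamma(k,
    theta) draws.  Returns ``(neuron, time_ms, amplitude)`` arrays sorted by
    time.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = n_neurons * stim.rate_hz * duration_ms / 1000.0
    k = rng.poisson(lam)
    nrn = rng.integers(0, n_neurons, k)
    t = rng.uniform(0.0, duration_ms, k)
    amp = stim.amplitude_gain * rng.gamma(stim.k, stim.theta, k)
    order = np.argsort(t, kind="stable")
    return nrn[order], t[order], amp[order]


# ---------------------------------------------------------------------------
# full simulation


def _csr(index: np.ndarray, n: int, m: int):
    """CSR pointers + edge-index array grouping edges by ``index`` (pre or post)."""
    order = np.argsort(index, kind="stable")
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr[1:], index, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, order.astype(np.int64)


class _CompiledTopology:
    """Kernel-ready arrays derived from a topology (cached on the topology)."""

    def __init__(self, topo: NetworkTopology, dt_ms: float):
        n, m = topo.n_neurons, topo.n_edges
        self.out_ptr, self.out_edge = _csr(topo.pre, n, m)
        self.in_ptr, self.in_edge = _csr(topo.post, n, m)
        self.e_pre = topo.pre.astype(np.int64)
        self.e_post = topo.post.astype(np.int64)
        self.e_delay = topo.delay_steps(dt_ms)
        exc = topo.kind == EXC
        self.e_is_ee = exc[topo.pre] & exc[topo.post]
        self.dt_ms = dt_ms


def compiled(topo: NetworkTopology, dt_ms: float) -> _CompiledTopology:
    cache = topo.meta.get("_compiled")
    if cache is None or cache.dt_ms != dt_ms or len(cache.e_pre) != topo.n_edges:
        cache = _CompiledTopology(topo, dt_ms)
        topo.meta["_compiled"] = cache
    return cache


def run_simulation(
    topology: NetworkTopology,
    state: SimState,
    duration_ms: float,
    stim: StimulusModel = StimulusModel(),
    sim: SimConfig = SimConfig(),
    stdp: STDPConfig | None = None,
    plasticity_on: bool = False,
    record: bool = True,
    seed=None,
    chunk_ms: float = 30000.0,
    extra_events=None,
) -> tuple[SpikeRaster, SimState]:
    """Advance ``state`` by ``duration_ms`` and return the spike raster.

    Per step: decay synaptic drive, deliver due delayed spikes (scaled by the
    target's desensitization), inject background events, Euler-step every
    neuron, enqueue outgoing spikes at ``t + delay`` with the current weight,
    update desensitization, and (when ``plasticity_on``) apply STDP at
    excitatory-excitatory synapses.  Weights in ``topology`` are modified in
    place when plasticity is on.  Deterministic given ``seed``.

    ``extra_events`` optionally injects deterministic current events as a
    ``(neuron_positions, times_ms, amplitudes)`` triple (times relative to the
    start of this call); they follow the same delivery mode as ``stim`` and
    are merged with the stochastic background.
    """
    if topology.n_neurons != len(state.v):
        raise ValueError("state size does not match topology")
    dt = sim.dt_ms
    n_steps_total = int(round(duration_ms / dt))
    if n_steps_total == 0:
        raster = SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), 0.0,
                             topology.ids.copy())
        return raster, state
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ct = compiled(topology, dt)
    n = topology.n_neurons

    stdp_on = bool(plasticity_on)
    if stdp_on:
        if stdp is None:
            stdp = STDPConfig(w_min=topology.meta.get("exc_scale", [0, 4])[0],
                              w_max=topology.meta.get("exc_scale", [0, 4])[1])
        timing = _kernel.STDP_ARRIVAL if stdp.timing == "arrival" else _kernel.STDP_EMISSION
        stdp_decay = math.exp(-dt / stdp.tau_ms)
        if timing == _kernel.STDP_ARRIVAL and len(state.etrace) != topology.n_edges:
            m = topology.n_edges
            state.etrace = np.zeros(m)
            state.etrace_step = np.full(m, state.step, dtype=np.int64)
            state.arr_cnt = np.zeros(m, dtype=np.int64)
            state.arr_step = np.full(m, -1, dtype=np.int64)
        ap, am, wmin, wmax = stdp.a_plus, stdp.a_minus, stdp.w_min, stdp.w_max
    else:
        timing, stdp_decay, ap, am, wmin, wmax = 0, 1.0, 0.0, 0.0, 0.0, 4.0

    syn_decay = math.exp(-dt / sim.tau_syn_ms)
    desens_decay = math.exp(-dt / sim.desens_tau_ms)
    ev_mode = _kernel.STIM_DECAY if stim.mode == "decay" else _kernel.STIM_IMPULSE

    etr = state.etrace if len(state.etrace) else np.zeros(0)
    etr_s = state.etrace_step if len(state.etrace_step) else np.zeros(0, dtype=np.int64)

    i_ext = np.zeros(n)
    spikers = np.zeros(n, dtype=np.int64)

    all_steps: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    step_start = state.step
    chunk_steps = max(int(round(chunk_ms / dt)), 1)
    done = 0
    # generous default: ~80 Hz sustained population rate
    rate_cap_hz = 80.0

    while done < n_steps_total:
        this_steps = min(chunk_steps, n_steps_total - done)
        # pre-draw background events for the chunk (absolute steps)
        ev_nrn, ev_t, ev_amp = (np.empty(0, dtype=np.int64), np.empty(0), np.empty(0))
        if stim.rate_hz > 0:
            ev_nrn, ev_t, ev_amp = background_events(n, this_steps * dt, stim, rng)
        if extra_events is not None:
            x_nrn, x_t, x_amp = (np.asarray(a) for a in extra_events)
            in_chunk = (x_t >= done * dt) & (x_t < (done + this_steps) * dt)
            ev_nrn = np.concatenate([ev_nrn, x_nrn[in_chunk].astype(np.int64)])
            ev_t = np.concatenate([ev_t, x_t[in_chunk] - done * dt])
            ev_amp = np.concatenate([ev_amp, x_amp[in_chunk].astype(float)])
            order = np.argsort(ev_t, kind="stable")
            ev_nrn, ev_t, ev_amp = ev_nrn[order], ev_t[order], ev_amp[order]
        ev_step = state.step + np.minimum((ev_t / dt).astype(np.int64), this_steps - 1)
        ev_nrn = ev_nrn.astype(np.int64)

        cap = max(int(n * this_steps * dt / 1000.0 * rate_cap_hz), 10000)
        while True:
            snapshot = _snapshot(state, topology)
            spk_step = np.zeros(cap, dtype=np.int64)
            spk_nrn = np.zeros(cap, dtype=np.int64)
            status, n_rec, _, last_step, bad = _kernel.simulate_chunk(
                this_steps, state.step, dt,
                state.v, state.u, state.g_exc, state.g_inh, state.s,
                topology.a, topology.b, topology.c, topology.d,
                syn_decay, sim.desens_floor, desens_decay, sim.spike_threshold_mv,
                ct.out_ptr, ct.out_edge, ct.in_ptr, ct.in_edge,
                ct.e_pre, ct.e_post, topology.weight, ct.e_delay, ct.e_is_ee,
                state.head, state.node_edge, state.node_next, state.free_stack, state.qstate,
                stdp_on, timing, state.x_trace, state.y_trace, stdp_decay, ap, am, wmin, wmax,
                etr, etr_s, state.arr_cnt, state.arr_step,
                ev_step, ev_nrn, ev_amp, ev_mode, 0,
                record, spk_step, spk_nrn,
                i_ext, spikers,
            )
            if status == _kernel.OK:
                break
            _restore(state, topology, snapshot)
            if status == _kernel.RECORD_FULL:
                cap *= 4
            elif status == _kernel.QUEUE_FULL:
                _grow_queue(state)
            else:
                raise NumericStateError(int(topology.ids[bad]), last_step * dt)
        if record and n_rec:
            all_steps.append(spk_step[:n_rec].copy())
            all_ids.append(spk_nrn[:n_rec].copy())
        state.step += this_steps
        done += this_steps

    if all_steps:
        steps = np.concatenate(all_steps)
        nrn = np.concatenate(all_ids)
        times = (steps - step_start) * dt
        ids = topology.ids[nrn]
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    raster = SpikeRaster(times, ids, n_steps_total * dt, topology.ids.copy())
    return raster, state


def _snapshot(state: SimState, topo: NetworkTopology):
    arrays = [state.v, state.u, state.g_exc, state.g_inh, state.s,
              state.x_trace, state.y_trace, state.head, state.node_edge,
              state.node_next, state.free_stack, state.qstate,
              state.etrace, state.etrace_step, state.arr_cnt, state.arr_step,
              topo.weight]
    return [a.copy() for a in arrays] + [state.step]


def _restore(state: SimState, topo: NetworkTopology, snap):
    (state.v[:], state.u[:], state.g_exc[:], state.g_inh[:], state.s[:],
     state.x_trace[:], state.y_trace[:], state.head[:], state.node_edge[:],
     state.node_next[:], state.free_stack[:], state.qstate[:]) = snap[:12]
    if len(state.etrace):
        state.etrace[:], state.etrace_step[:] = snap[12], snap[13]
        state.arr_cnt[:], state.arr_step[:] = snap[14], snap[15]
    topo.weight[:] = snap[16]
    state.step = snap[17]


def _grow_queue(state: SimState) -> None:
    old = len(state.node_edge)
    new = old * 2
    node_edge = np.zeros(new, dtype=np.int64)
    node_next = np.full(new, -1, dtype=np.int64)
    node_edge[:old] = state.node_edge
    node_next[:old] = state.node_next
    free_stack = np.zeros(new, dtype=np.int64)
    top = int(state.qstate[0])
    free_stack[:top + 1] = state.free_stack[:top + 1]
    free_stack[top + 1:top + 1 + (new - old)] = np.arange(old, new)
    state.node_edge = node_edge
    state.node_next = node_next
    state.free_stack = free_stack
    state.qstate[0] = top + (new - old)
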