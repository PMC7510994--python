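"""Additive spike-timing-dependent plasticity (Song model), E->E synapses only.

The network kernel applies STDP online through exponentially decaying
eligibility traces; this module holds the pairwise rule itself plus a small
step-by-step reference implementation (`TraceSTDP`) that operates on explicit
spike trains.  The trace formulation is mathematically equivalent to summing
the pairwise rule over all spike pairs, which the test suite verifies against
a brute-force oracle.
"""

from __future__ import annotations

import math

import numpy as np

from .config import STDPConfig
from .netgen import EXC, NetworkTopology


def stdp_delta(dt_post_pre_ms: float, cfg: STDPConfig = STDPConfig()) -> float:
    """Pairwise weight change for a single (pre, post) spike pair.

    ``dt = t_post - t_pre``.  Positive lags (pre before post) potentiate by
    ``A_plus * exp(-dt/tau)``; non-positive lags (including coincidence)
    depress by ``A_minus * exp(-|dt|/tau)``.
    """
    if not math.isfinite(dt_post_pre_ms):
        raise ValueError("spike-time difference must be finite")
    if dt_post_pre_ms > 0:
        return cfg.a_plus * math.exp(-dt_post_pre_ms / cfg.tau_ms)
    return -cfg.a_minus * math.exp(dt_post_pre_ms / cfg.tau_ms)


def ee_synapse_mask(topology: NetworkTopology) -> np.ndarray:
    """Boolean mask of edges eligible for STDP (excitatory pre *and* post)."""
    exc = topology.kind == EXC
    return exc[topology.pre] & exc[topology.post]


def check_registration(topology: NetworkTopology, edges: np.ndarray) -> None:
    """Reject any attempt to register a non-E->E synapse for plasticity."""
    ok = ee_synapse_mask(topology)
    if not np.all(ok[edges]):
        raise ValueError("STDP may only be registered at excitatory-excitatory synapses")


class TraceSTDP:
    """Online trace-based STDP for one synapse, on a fixed time grid.

    Maintains a pre trace ``x`` and post trace ``y`` that decay by
    ``exp(-dt/tau)`` each step.  Within a step, post spikes are added to ``y``
    before depression is applied (so coincident pairs fall on the depression
    branch), and pre spikes are added to ``x`` only after potentiation (so
    potentiation is strictly causal).  Equivalent to the all-pairs sum of
    :func:`stdp_delta` with hard clipping applied event by event.
    """

    def __init__(self, w0: float, cfg: STDPConfig = STDPConfig(), dt_ms: float = 0.2):
        self.w = float(w0)
        self.cfg = cfg
        self.dt = dt_ms
        self.decay = math.exp(-dt_ms / cfg.tau_ms)
        self.x = 0.0
        self.y = 0.0

    def step(self, pre_spike: bool, post_spike: bool) -> float:
        cfg = self.cfg
        self.x *= self.decay
        self.y *= self.decay
        if post_spike:
            self.y += 1.0
        if pre_spike:
            self.w = max(cfg.w_min, self.w - cfg.a_minus * self.y)
        if post_spike:
            self.w = min(cfg.w_max, self.w + cfg.a_plus * self.x)
        if pre_spike:
            self.x += 1.0
        return self.w

    def run(self, pre_steps, post_steps, n_steps: int) -> float:
        """Feed binary spike trains given as step indices; returns the final weight."""
        pre = set(int(i) for i in pre_steps)
        post = set(int(i) for i in post_steps)
        for t in range(n_steps):
            self.step(t in pre, t in post)
        return self.w


def apply_stdp(
    weights: np.ndarray,
    x_trace: np.ndarray,
    y_trace: np.ndarray,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    cfg: STDPConfig = STDPConfig(),
    dt_ms: float = 0.2,
) -> np.ndarray:
    """One synchronous STDP step over a set of synapses (vectorized reference).

    ``pre_spikes`` / ``post_spikes`` are boolean per-neuron flags for the
    current step; traces are decayed and updated in place.  Returns the
    clipped weights.  This mirrors exactly what the compiled kernel does each
    timestep when plasticity is enabled.
    """
    decay = math.exp(-dt_ms / cfg.tau_ms)
    x_trace *= decay
    y_trace *= decay
    y_trace[post_spikes] += 1.0
    dep = pre_spikes[pre_idx]
    weights[dep] = np.maximum(cfg.w_min, weights[dep] - cfg.a_minus * y_trace[post_idx[dep]])
    pot = post_spikes[post_idx]
    weights[pot] = np.minimum(cfg.w_max, weights[pot] + cfg.a_plus * x_trace[pre_idx[pot]])
    x_trace[pre_spikes] += 1.0
    return weights
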