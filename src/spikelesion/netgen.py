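"""Synthetic network substrate: neuron populations, spherical placement,
Erdos-Renyi-style random connectivity, bimodal weight seeding, and
arclength-proportional transmission delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import NetworkConfig

EXC = 1
INH = 0

#: Canonical Izhikevich parameters for the two cortical phenotypes:
#: regular-spiking (excitatory) and fast-spiking (inhibitory).
CANONICAL_PARAMS = {
    EXC: (0.02, 0.2, -65.0, 8.0),
    INH: (0.1, 0.2, -65.0, 2.0),
}


@dataclass
class NetworkTopology:
    """A weighted, delayed, directed network of Izhikevich neurons.

    Neurons are stored positionally; ``ids`` maps position to the original
    neuron id, which stays stable across injuries so rasters from before and
    after a lesion refer to the same cells.  Edges reference positions.
    """

    ids: np.ndarray          # (n,) int64, original neuron ids
    kind: np.ndarray         # (n,) int8, EXC or INH
    a: np.ndarray            # (n,) float64 Izhikevich parameters
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    positions: np.ndarray    # (n, 3) float64, unit vectors
    pre: np.ndarray          # (m,) int64, positional index of source neuron
    post: np.ndarray         # (m,) int64, positional index of target neuron
    weight: np.ndarray       # (m,) float64, signed synaptic strength
    delay_ms: np.ndarray     # (m,) float64, multiples of dt in (0, max_delay]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    @property
    def exc_mask(self) -> np.ndarray:
        return self.kind == EXC

    def delay_steps(self, dt_ms: float) -> np.ndarray:
        steps = np.rint(self.delay_ms / dt_ms).astype(np.int64)
        return np.maximum(steps, 1)

    def total_degree(self) -> np.ndarray:
        """In-degree plus out-degree per neuron."""
        deg = np.bincount(self.pre, minlength=self.n_neurons)
        deg = deg + np.bincount(self.post, minlength=self.n_neurons)
        return deg

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            ids=self.ids.copy(), kind=self.kind.copy(),
            a=self.a.copy(), b=self.b.copy(), c=self.c.copy(), d=self.d.copy(),
            positions=self.positions.copy(),
            pre=self.pre.copy(), post=self.post.copy(),
            weight=self.weight.copy(), delay_ms=self.delay_ms.copy(),
            meta=dict(self.meta),
        )

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_neurons
        if np.any(self.pre == self.post):
            raise ValueError("self-edges present")
        pairs = self.pre * n + self.post
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate edges present")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("positions not on the unit sphere")
        exc_edge = self.kind[self.pre] == EXC
        if np.any(self.weight[exc_edge] < 0) or np.any(self.weight[~exc_edge] > 0):
            raise ValueError("edge weight sign inconsistent with source kind")


def _require_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_positions(n: int, seed=None) -> np.ndarray:
    """Draw ``n`` points uniformly on the unit sphere (normalized Gaussian triples)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _require_rng(seed)
    pts = rng.standard_normal((n, 3))
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    # a resample for the (measure-zero) degenerate draw
    bad = norms[:, 0] < 1e-12
    while np.any(bad):
        pts[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(pts, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-12
    return pts / norms


def sample_neuron_params(kind: int, jitter: float = 0.05, seed=None, size: int | None = None):
    """Izhikevich (a, b, c, d) for one phenotype, with uniform per-neuron jitter.

    Values are centered on the canonical regular-spiking / fast-spiking
    parameterization; each parameter independently varies by up to
    ``+-jitter * |canonical|``.
    """
    if kind not in CANONICAL_PARAMS:
        raise ValueError(f"unknown neuron kind {kind!r}")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = _require_rng(seed)
    base = np.array(CANONICAL_PARAMS[kind])
    shape = (4,) if size is None else (size, 4)
    u = rng.uniform(-1.0, 1.0, shape)
    vals = base * (1.0 + jitter * u)
    if size is None:
        return tuple(vals)
    return vals


def build_connectivity(n: int, mean_degree: float, degree_cv: float = 0.1, seed=None):
    """Random directed edges with normally distributed out-degrees.

    Each neuron's out-degree is drawn from Normal(mean_degree/2,
    (degree_cv * mean_degree/2)^2), rounded and clipped to [1, n-1]; targets
    are chosen uniformly without replacement, excluding self.  In-degree then
    arises from random targeting, so total degree averages ``mean_degree``.

    Returns ``(pre, post)`` index arrays.
    """
    if mean_degree >= n:
        raise ValueError("mean_degree must be < n")
    rng = _require_rng(seed)
    mu = mean_degree / 2.0
    sigma = degree_cv * mu
    out_deg = np.rint(rng.normal(mu, sigma, n)).astype(np.int64)
    out_deg = np.clip(out_deg, 1, n - 1)
    pre = np.repeat(np.arange(n), out_deg)
    post = np.empty(pre.shape, dtype=np.int64)
    pos = 0
    others = np.arange(n)
    for i in range(n):
        k = out_deg[i]
        # uniform choice among the n-1 non-self targets, without replacement
        choice = rng.choice(n - 1, size=k, replace=False)
        choice[choice >= i] += 1
        post[pos:pos + k] = choice
        pos += k
    del others
    return pre, post


def seed_weights(
    pre: np.ndarray,
    kind: np.ndarray,
    exc_scale: tuple[float, float] = (0.0, 4.0),
    inh_scale: tuple[float, float] = (-14.0, 0.0),
    bimodal_beta: tuple[float, float] = (2.0, 8.0),
    inh_seed_sigma: float = 0.05,
    seed=None,
) -> np.ndarray:
    """Seed synaptic weights on the unit interval, then scale to physiology.

    Excitatory edges draw from a symmetric bimodal mixture on [0, 1] (equal-mass
    Beta lobes near 0 and 1, mimicking the bimodal fixed point that additive
    STDP drives weights toward) and are scaled to ``exc_scale``.  Inhibitory
    edges draw from Normal(0.5, inh_seed_sigma) clipped to [0, 1] and are
    mapped linearly onto ``inh_scale``.
    """
    for lo, hi in (exc_scale, inh_scale):
        if lo > hi:
            raise ValueError("scale bounds must satisfy lo <= hi")
    rng = _require_rng(seed)
    m = len(pre)
    exc_edge = kind[pre] == EXC
    w = np.empty(m, dtype=np.float64)

    n_exc = int(exc_edge.sum())
    a_lobe, b_lobe = bimodal_beta
    low_lobe = rng.random(n_exc) < 0.5
    u = np.where(
        low_lobe,
        rng.beta(a_lobe, b_lobe, n_exc),
        1.0 - rng.beta(a_lobe, b_lobe, n_exc),
    )
    lo, hi = exc_scale
    w[exc_edge] = lo + u * (hi - lo)

    n_inh = m - n_exc
    u_inh = np.clip(rng.normal(0.5, inh_seed_sigma, n_inh), 0.0, 1.0)
    lo, hi = inh_scale
    w[~exc_edge] = lo + u_inh * (hi - lo)
    return w


def compute_delays(
    positions: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    max_delay_ms: float = 8.0,
    dt_ms: float = 0.2,
) -> np.ndarray:
    """Transmission delays proportional to great-circle distance.

    ``delay = max_delay * arclength / pi``, rounded *up* to the dt grid with a
    one-step floor (coincident neurons get the minimum delay; a zero delay
    would break event ordering).  All results lie in (0, max_delay].
    """
    dots = np.einsum("ij,ij->i", positions[pre], positions[post])
    arc = np.arccos(np.clip(dots, -1.0, 1.0))
    raw = max_delay_ms * arc / np.pi
    steps = np.ceil(raw / dt_ms - 1e-12).astype(np.int64)
    steps = np.maximum(steps, 1)
    return steps * dt_ms


def build_network(cfg: NetworkConfig = NetworkConfig(), seed=None) -> NetworkTopology:
    """Construct a complete synthetic microcircuit from a :class:`NetworkConfig`.

    Deterministic given ``seed``.  Excitatory neurons occupy the first
    ``round(frac_exc * n)`` positions.
    """
    if cfg.topology_mode != "random":
        raise NotImplementedError("only topology_mode='random' is implemented")
    rng = _require_rng(seed)
    n = cfg.n
    n_exc = int(round(cfg.frac_exc * n))
    kind = np.full(n, INH, dtype=np.int8)
    kind[:n_exc] = EXC

    positions = sample_positions(n, rng)
    params = np.empty((n, 4))
    params[:n_exc] = sample_neuron_params(EXC, cfg.param_jitter, rng, size=n_exc)
    if n - n_exc:
        params[n_exc:] = sample_neuron_params(INH, cfg.param_jitter, rng, size=n - n_exc)

    pre, post = build_connectivity(n, cfg.mean_degree, cfg.degree_cv, rng)
    weight = seed_weights(
        pre, kind, cfg.exc_scale, cfg.inh_scale,
        cfg.bimodal_beta, cfg.inh_seed_sigma, rng,
    )
    delay_ms = compute_delays(positions, pre, post, cfg.max_delay_ms, cfg.dt_ms)

    topo = NetworkTopology(
        ids=np.arange(n, dtype=np.int64),
        kind=kind,
        a=params[:, 0], b=params[:, 1], c=params[:, 2], d=params[:, 3],
        positions=positions,
        pre=pre, post=post, weight=weight, delay_ms=delay_ms,
        meta={
            "n": n, "frac_exc": cfg.frac_exc, "mean_degree": cfg.mean_degree,
            "degree_cv": cfg.degree_cv, "exc_scale": list(cfg.exc_scale),
            "inh_scale": list(cfg.inh_scale), "max_delay_ms": cfg.max_delay_ms,
            "dt_ms": cfg.dt_ms, "param_jitter": cfg.param_jitter,
        },
    )
    return topo
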