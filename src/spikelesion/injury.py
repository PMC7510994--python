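"""Neurodegeneration protocols: random (E/I-ratio preserving), focal
(spatially contiguous lesion on the sphere), and activity-ranked (LFR/HFR)
deletion of excitatory neurons.

Deletion is destructive and complete: removed neurons disappear from the
neuron table together with every incident edge, and any spikes they had in
flight are purged (subsequent simulations start from a cleared delay queue).
Original neuron ids are preserved on the survivors.
"""

from __future__ import annotations

import numpy as np

from .netgen import EXC, INH, NetworkTopology


def _subset(topology: NetworkTopology, delete_pos: np.ndarray) -> tuple[NetworkTopology, np.ndarray]:
    """Remove neurons at positional indices ``delete_pos``; return (topology', deleted ids)."""
    n = topology.n_neurons
    keep = np.ones(n, dtype=bool)
    keep[delete_pos] = False
    new_index = np.cumsum(keep) - 1
    edge_keep = keep[topology.pre] & keep[topology.post]
    meta = {k: v for k, v in topology.meta.items() if not k.startswith("_")}
    meta["n_surviving"] = int(keep.sum())
    out = NetworkTopology(
        ids=topology.ids[keep].copy(),
        kind=topology.kind[keep].copy(),
        a=topology.a[keep].copy(), b=topology.b[keep].copy(),
        c=topology.c[keep].copy(), d=topology.d[keep].copy(),
        positions=topology.positions[keep].copy(),
        pre=new_index[topology.pre[edge_keep]],
        post=new_index[topology.post[edge_keep]],
        weight=topology.weight[edge_keep].copy(),
        delay_ms=topology.delay_ms[edge_keep].copy(),
        meta=meta,
    )
    return out, topology.ids[delete_pos].copy()


def _n_delete(fraction: float, n_original: int) -> int:
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return int(round(fraction * n_original))


def injure_random(topology: NetworkTopology, fraction: float, seed=None):
    """Random deletion preserving the E/I ratio: 4 excitatory per 1 inhibitory.

    ``n_del = round(fraction * n)`` neurons are removed, ``round(0.8 * n_del)``
    of them excitatory and the rest inhibitory, chosen uniformly within kind.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = topology.n_neurons
    n_del = _n_delete(fraction, n)
    if n_del == 0:
        return topology.copy(), np.empty(0, dtype=np.int64)
    n_exc_del = int(round(0.8 * n_del))
    n_inh_del = n_del - n_exc_del
    exc_pos = np.flatnonzero(topology.kind == EXC)
    inh_pos = np.flatnonzero(topology.kind == INH)
    if n_exc_del > len(exc_pos) or n_inh_del > len(inh_pos):
        raise ValueError("requested deletions exceed available neurons of a kind")
    delete = np.concatenate([
        rng.choice(exc_pos, n_exc_del, replace=False),
        rng.choice(inh_pos, n_inh_del, replace=False),
    ])
    return _subset(topology, delete)


def injure_focal(topology: NetworkTopology, fraction: float, seed=None):
    """Spatially contiguous lesion: delete the neurons nearest a random center.

    A lesion center is drawn uniformly on the sphere and the ``n_del`` neurons
    with the smallest arclength to it are removed regardless of kind.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = topology.n_neurons
    n_del = _n_delete(fraction, n)
    if n_del == 0:
        return topology.copy(), np.empty(0, dtype=np.int64)
    center = rng.standard_normal(3)
    center /= np.linalg.norm(center)
    arc = np.arccos(np.clip(topology.positions @ center, -1.0, 1.0))
    delete = np.argsort(arc, kind="stable")[:n_del]
    return _subset(topology, delete)


def injure_by_rate(topology: NetworkTopology, fraction: float, mode: str,
                   rate_table: dict | np.ndarray, seed=None):
    """Activity-ranked deletion of excitatory neurons only.

    ``mode="lfr"`` removes the excitatory neurons with the lowest measured
    firing rates, ``mode="hfr"`` the highest; inhibitory neurons are never
    touched.  ``rate_table`` maps original neuron id to rate (dict or dense
    array indexed by id) and must cover every excitatory neuron.  Ties are
    broken by a seeded random shuffle.
    """
    if mode not in ("lfr", "hfr"):
        raise ValueError(f"mode must be 'lfr' or 'hfr', got {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = topology.n_neurons
    n_del = _n_delete(fraction, n)
    if n_del == 0:
        return topology.copy(), np.empty(0, dtype=np.int64)
    exc_pos = np.flatnonzero(topology.kind == EXC)
    if n_del > len(exc_pos):
        raise ValueError("requested deletions exceed the excitatory population")
    if isinstance(rate_table, dict):
        try:
            rates = np.array([rate_table[int(i)] for i in topology.ids[exc_pos]], dtype=float)
        except KeyError as err:
            raise ValueError(f"rate_table missing excitatory neuron id {err}") from None
    else:
        rate_table = np.asarray(rate_table, dtype=float)
        ids = topology.ids[exc_pos]
        if ids.max() >= len(rate_table):
            raise ValueError("rate_table does not cover all excitatory neurons")
        rates = rate_table[ids]
    # random tie-break: shuffle before the stable sort
    perm = rng.permutation(len(exc_pos))
    order = perm[np.argsort(rates[perm], kind="stable")]
    if mode == "hfr":
        order = order[::-1]
    delete = exc_pos[order[:n_del]]
    return _subset(topology, delete)


def subset_state(state, keep_ids: np.ndarray, old_ids: np.ndarray, new_topology, sim_cfg):
    """Carry surviving neurons' membrane state into a lesioned network.

    Membrane potentials, recovery variables, synaptic drive and
    desensitization factors of survivors are preserved; the delay queue and
    plasticity traces are cleared (in-flight spikes are purged with the
    lesion).
    """
    from .dynamics import init_state

    pos_of_id = {int(i): p for p, i in enumerate(old_ids)}
    sel = np.array([pos_of_id[int(i)] for i in keep_ids], dtype=np.int64)
    new = init_state(new_topology, sim_cfg)
    new.v[:] = state.v[sel]
    new.u[:] = state.u[sel]
    new.g_exc[:] = state.g_exc[sel]
    new.g_inh[:] = state.g_inh[sel]
    new.s[:] = state.s[sel]
    return new
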