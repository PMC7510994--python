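"""Shared fixtures: hand-built micro-topologies and the scaled-down
injury/recovery experiment reused by the directional tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import spikelesion as sl
from spikelesion.netgen import EXC, INH, NetworkTopology


def make_topology(kinds, edges, positions=None, dt_ms=0.2, max_delay_ms=8.0,
                  jitter=0.0, seed=0):
    """Tiny explicit topology: ``kinds`` is a string like 'EEI',
    ``edges`` a list of (pre, post, weight, delay_ms)."""
    n = len(kinds)
    kind = np.array([EXC if k == "E" else INH for k in kinds], dtype=np.int8)
    params = np.array([
        sl.sample_neuron_params(int(k), jitter, np.random.default_rng(seed + i))
        for i, k in enumerate(kind)
    ])
    if positions is None:
        positions = sl.sample_positions(n, seed)
    if edges:
        pre = np.array([e[0] for e in edges], dtype=np.int64)
        post = np.array([e[1] for e in edges], dtype=np.int64)
        weight = np.array([e[2] for e in edges], dtype=float)
        delay = np.array([e[3] for e in edges], dtype=float)
    else:
        pre = post = np.empty(0, dtype=np.int64)
        weight = delay = np.empty(0)
    return NetworkTopology(
        ids=np.arange(n, dtype=np.int64), kind=kind,
        a=params[:, 0], b=params[:, 1], c=params[:, 2], d=params[:, 3],
        positions=np.asarray(positions, dtype=float),
        pre=pre, post=post, weight=weight, delay_ms=delay,
        meta={"n": n, "dt_ms": dt_ms, "max_delay_ms": max_delay_ms,
              "exc_scale": [0.0, 4.0], "inh_scale": [-14.0, 0.0]},
    )


FORCE_AMP = 2000.0  # impulse current guaranteed to fire any neuron from rest


def forced_spike_sim(topo, spike_times: dict[int, list[float]], duration_ms,
                     plasticity_on=False, stdp=None, sim=None, stim_mode="impulse"):
    """Run a network with spikes forced at given times via huge impulses."""
    sim = sim or sl.SimConfig()
    nrn, t, amp = [], [], []
    for i, times in spike_times.items():
        for tt in times:
            nrn.append(i)
            t.append(tt)
            amp.append(FORCE_AMP)
    stim = sl.StimulusModel(rate_hz=0.0, mode=stim_mode)
    state = sl.init_state(topo, sim)
    raster, state = sl.run_simulation(
        topo, state, duration_ms, stim, sim, stdp,
        plasticity_on=plasticity_on, record=True, seed=0,
        extra_events=(np.array(nrn), np.array(t), np.array(amp)),
    )
    return raster, state


# ---------------------------------------------------------------------------
# scaled-down directional experiment (shared by several tests)

DESK_N = 300
DESK_REPLICATES = 5


@pytest.fixture(scope="session")
def directional_results():
    """Injury/recovery outcomes on reduced networks, per replicate.

    Five replicates of: build (n=300, full connectivity statistics), settle
    with STDP (30 sim-min cap), then independently apply random deletion at
    20/50/80 % (with a 15-min STDP recovery at 50 %) and LFR/HFR deletion at
    10 %, measuring 5-minute windows with frozen weights.  The oscillation
    detector is pinned to the intact network size throughout.
    """
    cfg = sl.desk_scale(n=DESK_N, settle_max_min=30.0, recovery_max_min=15.0,
                        n_replicates=DESK_REPLICATES)
    mc = sl.pinned_metrics(cfg, DESK_N)
    rows = []
    root = np.random.SeedSequence(20250925)
    for rep, child in enumerate(root.spawn(DESK_REPLICATES)):
        sb, ss, si, sm, sr = (np.random.default_rng(c) for c in child.spawn(5))
        topo = sl.build_network(cfg.network, sb)
        state = sl.init_state(topo, cfg.sim)
        settled = sl.settle(topo, state, cfg, ss, metrics_cfg=mc)
        base = sl.summarize(settled.raster, cfg=mc)
        rates, _ = sl.firing_rate(settled.raster)
        idx = sl.connectivity_index(topo)
        exc = topo.exc_mask & ~np.isnan(idx)
        r_exc = float(np.corrcoef(idx[exc], rates[exc])[0, 1])
        rate_by_id = np.zeros(topo.n_neurons)
        rate_by_id[settled.raster.neuron_ids] = rates

        rec = {"replicate": rep, "baseline": base, "index_rate_r": r_exc,
               "ee_weights": topo.weight[sl.ee_synapse_mask(topo)].copy()}
        conditions = [("random", 0.2, False), ("random", 0.5, True),
                      ("random", 0.8, False), ("lfr", 0.1, False), ("hfr", 0.1, False)]
        for mode, frac, recover in conditions:
            if mode == "random":
                t2, _ = sl.injure_random(topo, frac, si)
            else:
                t2, _ = sl.injure_by_rate(topo, frac, mode, rate_by_id, si)
            st2 = sl.subset_state(state, t2.ids, topo.ids, t2, cfg.sim)
            w_before = t2.weight.copy()
            raster, st2 = sl.run_simulation(
                t2, st2, cfg.measure_window_min * 60000.0, cfg.stimulus, cfg.sim,
                plasticity_on=False, record=True, seed=sm)
            rec[f"{mode}@{frac}"] = sl.summarize(raster, cfg=mc)
            rec[f"{mode}@{frac}:frozen"] = bool(np.array_equal(w_before, t2.weight))
            if recover:
                rcfg = replace(cfg, settle_max_min=cfg.recovery_max_min)
                rr = sl.settle(t2, st2, rcfg, sr, metrics_cfg=mc)
                rec[f"{mode}@{frac}:recovered"] = sl.summarize(rr.raster, cfg=mc)
        rows.append(rec)
    return rows


def group_mean(rows, key, field="firing_rate_hz"):
    vals = [getattr(r[key], field) for r in rows]
    return float(np.nanmean(vals))
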