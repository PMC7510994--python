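"""Lesion a settled network and let plasticity restructure it.

Settles a reduced network, removes 50 % of its neurons at random (4
excitatory per 1 inhibitory, preserving E/I balance), measures the immediate
deficit with frozen weights, then lets STDP rebalance the surviving synapses
and measures again.  Activity drops sharply after injury and partially
recovers with plasticity.
"""

from dataclasses import replace

import numpy as np

import spikelesion as sl

cfg = sl.desk_scale(n=300, settle_max_min=30.0, recovery_max_min=15.0)
mc = sl.pinned_metrics(cfg, cfg.network.n)

topo = sl.build_network(cfg.network, seed=1)
state = sl.init_state(topo, cfg.sim)
res = sl.settle(topo, state, cfg, np.random.default_rng(2), metrics_cfg=mc)
base = sl.summarize(res.raster, cfg=mc)

injured, deleted = sl.injure_random(topo, 0.5, seed=3)
print(f"deleted {len(deleted)} of {topo.n_neurons} neurons "
      f"({(topo.kind[deleted] == sl.EXC).sum()} excitatory)")

st = sl.subset_state(state, injured.ids, topo.ids, injured, cfg.sim)
raster, st = sl.run_simulation(injured, st, 300_000.0, cfg.stimulus, cfg.sim,
                               plasticity_on=False, seed=4)
frozen = sl.summarize(raster, cfg=mc)

rec = sl.settle(injured, st, replace(cfg, settle_max_min=cfg.recovery_max_min),
                np.random.default_rng(5), metrics_cfg=mc)
after = sl.summarize(rec.raster, cfg=mc)

print(f"{'phase':<16}{'rate Hz':>9}{'osc /s':>9}{'peak %':>9}")
for name, m in (("baseline", base), ("post-injury", frozen),
                ("post-plasticity", after)):
    print(f"{name:<16}{m.firing_rate_hz:>9.2f}{m.osc_freq_hz:>9.1f}"
          f"{100 * m.osc_magnitude_frac:>9.1f}")
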