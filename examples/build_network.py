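"""Build a baseline cortical microcircuit and inspect its structure.

Constructs the default 1000-neuron network (80 % regular-spiking excitatory,
20 % fast-spiking inhibitory, ~100 connections per neuron, delays up to 8 ms)
and prints the structural summary statistics.
"""

import numpy as np

import spikelesion as sl

topo = sl.build_network(sl.NetworkConfig(), seed=1)
topo.validate()

deg = topo.total_degree()
exc_edge = topo.kind[topo.pre] == sl.EXC
print(f"neurons: {topo.n_neurons} ({topo.exc_mask.mean():.0%} excitatory)")
print(f"edges:   {topo.n_edges}")
print(f"mean total degree: {deg.mean():.1f} (sd {deg.std():.1f})")
print(f"excitatory weights in [{topo.weight[exc_edge].min():.2f}, "
      f"{topo.weight[exc_edge].max():.2f}]")
print(f"inhibitory weights in [{topo.weight[~exc_edge].min():.2f}, "
      f"{topo.weight[~exc_edge].max():.2f}]")
print(f"delays: {topo.delay_ms.min():.1f}-{topo.delay_ms.max():.1f} ms "
      f"(quantized to 0.2 ms)")

# the excitatory seed distribution is bimodal: most mass sits near the bounds,
# mimicking the fixed point that additive STDP drives weights toward
we = topo.weight[exc_edge]
print(f"excitatory weight mass near bounds (<1 or >3): "
      f"{np.mean((we < 1) | (we > 3)):.0%}")
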