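"""Plain-text and HDF5 serialization for topologies, rasters and result tables.

Text formats are tab-separated with ``#``-prefixed header lines; the HDF5
container mirrors the topology in groups ``/neurons``, ``/edges`` and
``/meta``.  All writers round-trip exactly through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import SpikeRaster
from .netgen import NetworkTopology


def _clean_meta(meta: dict) -> dict:
    return {k: v for k, v in meta.items() if not k.startswith("_")}


def write_topology_tsv(topo: NetworkTopology, edge_path, neuron_path) -> None:
    """Edge list + neuron table as two TSV files (headers in '#' lines)."""
    meta = json.dumps(_clean_meta(topo.meta))
    with open(edge_path, "w") as fh:
        fh.write(f"# spikelesion edges\t{meta}\n")
        fh.write("# pre_id\tpost_id\tweight\tdelay_ms\n")
        for p, q, w, d in zip(topo.ids[topo.pre], topo.ids[topo.post],
                              topo.weight, topo.delay_ms):
            fh.write(f"{p}\t{q}\t{float(w)!r}\t{float(d)!r}\n")
    with open(neuron_path, "w") as fh:
        fh.write("# spikelesion neurons\n")
        fh.write("# id\tkind\ta\tb\tc\td\tx\ty\tz\n")
        for i in range(topo.n_neurons):
            x, y, z = topo.positions[i]
            fh.write(f"{topo.ids[i]}\t{int(topo.kind[i])}\t{float(topo.a[i])!r}\t{float(topo.b[i])!r}"
                     f"\t{float(topo.c[i])!r}\t{float(topo.d[i])!r}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def read_topology_tsv(edge_path, neuron_path) -> NetworkTopology:
    with open(edge_path) as fh:
        first = fh.readline()
        meta = {}
        if "\t" in first:
            meta = json.loads(first.split("\t", 1)[1])
        edata = np.loadtxt(fh, comments="#", ndmin=2)
    ndata = np.loadtxt(neuron_path, comments="#", ndmin=2)
    ids = ndata[:, 0].astype(np.int64)
    pos_of_id = {int(v): k for k, v in enumerate(ids)}
    if len(edata):
        pre = np.array([pos_of_id[int(v)] for v in edata[:, 0]], dtype=np.int64)
        post = np.array([pos_of_id[int(v)] for v in edata[:, 1]], dtype=np.int64)
        weight, delay = edata[:, 2], edata[:, 3]
    else:
        pre = post = np.empty(0, dtype=np.int64)
        weight = delay = np.empty(0)
    return NetworkTopology(
        ids=ids, kind=ndata[:, 1].astype(np.int8),
        a=ndata[:, 2], b=ndata[:, 3], c=ndata[:, 4], d=ndata[:, 5],
        positions=ndata[:, 6:9].copy(),
        pre=pre, post=post, weight=weight, delay_ms=delay, meta=meta,
    )


def write_topology_hdf5(topo: NetworkTopology, path) -> None:
    """Single-file structured container: /neurons, /edges, /meta."""
    with h5py.File(path, "w") as f:
        g = f.create_group("neurons")
        g.create_dataset("id", data=topo.ids)
        g.create_dataset("kind", data=topo.kind)
        for name in "abcd":
            g.create_dataset(name, data=getattr(topo, name))
        g.create_dataset("position", data=topo.positions)
        e = f.create_group("edges")
        e.create_dataset("pre", data=topo.pre)
        e.create_dataset("post", data=topo.post)
        e.create_dataset("weight", data=topo.weight)
        e.create_dataset("delay_ms", data=topo.delay_ms)
        f.create_group("meta").attrs["json"] = json.dumps(_clean_meta(topo.meta))


def read_topology_hdf5(path) -> NetworkTopology:
    with h5py.File(path, "r") as f:
        g, e = f["neurons"], f["edges"]
        return NetworkTopology(
            ids=g["id"][:], kind=g["kind"][:],
            a=g["a"][:], b=g["b"][:], c=g["c"][:], d=g["d"][:],
            positions=g["position"][:],
            pre=e["pre"][:], post=e["post"][:],
            weight=e["weight"][:], delay_ms=e["delay_ms"][:],
            meta=json.loads(f["meta"].attrs["json"]),
        )


def write_raster(raster: SpikeRaster, path) -> None:
    """Raster TSV: neuron_id, time_ms rows sorted by time, '#' header."""
    header = {
        "duration_ms": raster.duration_ms,
        "n_neurons": raster.n_neurons,
        "neuron_ids": raster.neuron_ids.tolist(),
    }
    order = np.argsort(raster.times_ms, kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# spikelesion raster\t{json.dumps(header)}\n")
        fh.write("# neuron_id\ttime_ms\n")
        for i in order:
            fh.write(f"{raster.ids[i]}\t{float(raster.times_ms[i])!r}\n")


def read_raster(path) -> SpikeRaster:
    with open(path) as fh:
        header = json.loads(fh.readline().split("\t", 1)[1])
        data = np.loadtxt(fh, comments="#", ndmin=2)
    if data.size:
        ids = data[:, 0].astype(np.int64)
        times = data[:, 1]
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    return SpikeRaster(
        times_ms=times, ids=ids,
        duration_ms=header["duration_ms"],
        neuron_ids=np.asarray(header["neuron_ids"], dtype=np.int64),
    )


def write_deleted_ids(deleted: np.ndarray, path) -> None:
    Path(path).write_text("\n".join(str(int(i)) for i in deleted) + "\n")
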