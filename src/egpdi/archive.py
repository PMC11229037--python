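"""HDF5 graph archive: one group per protein holding X, sparse adjacency,
coordinates, edge features and optional labels.

Layout (one group per protein, keyed by protein name):

    /<name>/X           [L, 6524] float32   node features
    /<name>/edge_index  [d_e, 2]  int64     undirected edges, i < j
    /<name>/coords      [L, 3]    float64   node coordinates (Å)
    /<name>/E           [d_e, 2]  float64   (distance Å, angle cosine)
    /<name>/y           [L]       int8      labels (absent if unlabelled)
    /<name>.attrs["L"]                      residue count

Root attrs record the feature-block column offsets.  Datasets are written
with track_times=False so regenerating a corpus under the same seed yields a
byte-identical file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .features import block_offsets
from .structure import ProteinGraph

__all__ = ["save_corpus", "load_corpus"]


def _dense_adjacency(edge_index: np.ndarray, L: int) -> np.ndarray:
    A = np.zeros((L, L), dtype=np.int8)
    if edge_index.size:
        i, j = edge_index[:, 0], edge_index[:, 1]
        A[i, j] = 1
        A[j, i] = 1
    return A


def save_corpus(graphs: list[ProteinGraph], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["block_offsets"] = json.dumps(block_offsets())
        for g in graphs:
            grp = f.create_group(g.name)
            grp.attrs["L"] = g.n_residues
            grp.attrs["sequence"] = g.sequence
            kw = {"track_times": False}
            grp.create_dataset("X", data=np.asarray(g.X, dtype=np.float32), **kw)
            grp.create_dataset("edge_index", data=g.edge_index.astype(np.int64), **kw)
            grp.create_dataset("coords", data=g.coords.astype(np.float64), **kw)
            grp.create_dataset("E", data=g.E.astype(np.float64), **kw)
            if g.y is not None:
                grp.create_dataset("y", data=np.asarray(g.y, dtype=np.int8), **kw)


def load_corpus(path: str | Path) -> list[ProteinGraph]:
    graphs: list[ProteinGraph] = []
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            L = int(grp.attrs["L"])
            edge_index = np.asarray(grp["edge_index"], dtype=np.int64)
            graphs.append(ProteinGraph(
                X=np.asarray(grp["X"], dtype=np.float64),
                A=_dense_adjacency(edge_index, L),
                coords=np.asarray(grp["coords"], dtype=np.float64),
                edge_index=edge_index,
                E=np.asarray(grp["E"], dtype=np.float64),
                y=np.asarray(grp["y"], dtype=np.int8) if "y" in grp else None,
                name=name,
                sequence=str(grp.attrs.get("sequence", "")),
            ))
    return graphs
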