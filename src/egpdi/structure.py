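"""Residue-level geometric graphs from protein structures.

A protein chain is turned into a graph whose nodes are residues.  Two
residues are connected when their side-chain centroids lie closer than a
distance cutoff (17 Å by default), each edge carries the inter-node
Euclidean distance and the cosine of the angle between the two residues'
side-chain orientation vectors, and each node carries its 3-D coordinate
(CA by default) for the equivariant branch.  Binding labels come from
proximity of residue atoms to DNA atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueStructure",
    "ProteinGraph",
    "parse_structure",
    "chain_atom_coords",
    "side_chain_centroid",
    "build_adjacency",
    "compute_edge_features",
    "label_binding_sites",
    "build_graph",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_LABEL_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 17.0  # Å, side-chain-centroid contact radius
DEFAULT_LABEL_CUTOFF = 0.5  # Å, minimum atomic distance defining a binding residue

_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    res_name: str
    res_index: int
    atoms: list[Atom] = field(default_factory=list)

    def atom_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=np.float64)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ResidueStructure:
    """An ordered protein chain with per-residue atom records."""

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(
            gemmi.find_tabulated_residue(r.res_name).one_letter_code.upper()
            if gemmi.find_tabulated_residue(r.res_name) else "X"
            for r in self.residues
        )


@dataclass
class ProteinGraph:
    """Node features, adjacency, coordinates and edge features of one protein.

    `edge_index` stores each undirected edge once as (i, j) with i < j;
    `E[k]` holds (Euclidean distance Å, orientation-angle cosine) for edge k.
    """

    X: np.ndarray | None  # [L, 6524] node features (may be attached later)
    A: np.ndarray  # [L, L] binary adjacency
    coords: np.ndarray  # [L, 3] Å
    edge_index: np.ndarray  # [d_e, 2], i < j
    E: np.ndarray  # [d_e, 2]
    y: np.ndarray | None = None  # [L] binary labels
    name: str = ""
    sequence: str = ""  # one-letter residue codes, "" if unknown

    @property
    def n_residues(self) -> int:
        return self.A.shape[0]


def parse_structure(pdb_path: str | Path, chain: str) -> ResidueStructure:
    """Parse one protein chain from a PDB file.

    Only the first model is read; HETATM records and waters are excluded;
    for alternate locations the highest-occupancy conformer of each atom
    name is retained.
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(str(pdb_path))
    structure = gemmi.read_pdb(str(pdb_path))
    if len(structure) == 0:
        raise ValueError(f"no models in {pdb_path}")
    model = structure[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise ValueError(f"chain not found: {chain!r} in {pdb_path}")

    residues: list[Residue] = []
    for gres in gchain:
        if gres.het_flag != "A":  # ATOM records only: skip HETATM and waters
            continue
        best: dict[str, Atom] = {}
        for ga in gres:
            atom = Atom(
                name=ga.name,
                element=ga.element.name,
                xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                occupancy=ga.occ,
                altloc=ga.altloc,
            )
            prev = best.get(ga.name)
            if prev is None or atom.occupancy > prev.occupancy:
                best[ga.name] = atom
        if best:
            residues.append(
                Residue(res_name=gres.name, res_index=gres.seqid.num,
                        atoms=list(best.values()))
            )
    if not residues:
        raise ValueError(f"chain {chain!r} contains no standard protein residues")
    residues.sort(key=lambda r: r.res_index)
    return ResidueStructure(chain_id=chain, residues=residues)


def chain_atom_coords(pdb_path: str | Path, chain: str) -> np.ndarray:
    """All atom coordinates of a chain (e.g. a DNA chain used for labelling)."""
    structure = gemmi.read_pdb(str(Path(pdb_path)))
    model = structure[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise ValueError(f"chain not found: {chain!r} in {pdb_path}")
    coords = [
        [a.pos.x, a.pos.y, a.pos.z]
        for res in gchain
        if res.name != "HOH"
        for a in res
    ]
    if not coords:
        raise ValueError(f"chain {chain!r} has no atoms")
    return np.asarray(coords, dtype=np.float64)


def side_chain_centroid(residue: Residue) -> np.ndarray:
    """Unweighted mean of heavy side-chain atoms; CA fallback for glycine.

    Side-chain atoms are all atoms except the backbone (N, CA, C, O) and
    hydrogens.  Residues without any side-chain heavy atom fall back to
    their CA coordinate.
    """
    side = [a.xyz for a in residue.atoms
            if a.name not in _BACKBONE and a.element != "H"]
    if side:
        return np.mean(np.asarray(side, dtype=np.float64), axis=0)
    ca = residue.get_atom("CA")
    if ca is not None:
        return np.asarray(ca.xyz, dtype=np.float64)
    heavy = [a.xyz for a in residue.atoms if a.element != "H"]
    if heavy:
        return np.mean(np.asarray(heavy, dtype=np.float64), axis=0)
    raise ValueError(f"residue {residue.res_name}{residue.res_index} has no heavy atoms")


def build_adjacency(centroids: np.ndarray,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Binary contact map: A_ij = 1 iff i != j and ||c_i - c_j|| < cutoff."""
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.ndim != 2 or centroids.shape[1] != 3:
        raise ValueError("centroids must have shape [L, 3]")
    if not np.isfinite(centroids).all():
        raise ValueError("non-finite coordinates in centroids")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    A = (dist < cutoff).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def edges_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Undirected edge list, one (i, j) record per i < j pair."""
    iu, ju = np.nonzero(np.triu(A, k=1))
    return np.stack([iu, ju], axis=1).astype(np.int64)


def compute_edge_features(coords: np.ndarray, edge_index: np.ndarray,
                          orientations: np.ndarray | None = None) -> np.ndarray:
    """Per-edge (distance, angle cosine) features.

    `coords` are the node positions used for the distance column.  The
    cosine column is the angle between the two residues' orientation
    vectors (CA -> side-chain centroid); edges with a degenerate
    (zero-length) orientation vector get cosine 0.
    """
    coords = np.asarray(coords, dtype=np.float64)
    edge_index = np.asarray(edge_index, dtype=np.int64)
    if edge_index.size == 0:
        return np.zeros((0, 2), dtype=np.float64)
    i, j = edge_index[:, 0], edge_index[:, 1]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)

    if orientations is None:
        cos = np.zeros_like(d)
    else:
        orientations = np.asarray(orientations, dtype=np.float64)
        u, v = orientations[i], orientations[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        ok = (nu > 1e-12) & (nv > 1e-12)
        cos = np.zeros_like(d)
        cos[ok] = (u[ok] * v[ok]).sum(axis=1) / (nu[ok] * nv[ok])
        cos = np.clip(cos, -1.0, 1.0)
    return np.stack([d, cos], axis=1)


def residue_orientations(structure: ResidueStructure) -> np.ndarray:
    """CA -> side-chain-centroid vector per residue (zeros when degenerate)."""
    out = np.zeros((len(structure), 3), dtype=np.float64)
    for k, res in enumerate(structure.residues):
        ca = res.get_atom("CA")
        if ca is None:
            continue
        out[k] = side_chain_centroid(res) - ca.xyz
    return out


def label_binding_sites(protein: ResidueStructure, dna_atoms: np.ndarray,
                        cutoff: float = DEFAULT_LABEL_CUTOFF) -> np.ndarray:
    """y_i = 1 iff the smallest atomic distance of residue i to DNA < cutoff."""
    dna_atoms = np.asarray(dna_atoms, dtype=np.float64)
    if dna_atoms.size == 0:
        raise ValueError("empty DNA atom list")
    dna_atoms = dna_atoms.reshape(-1, 3)
    y = np.zeros(len(protein), dtype=np.int8)
    for k, res in enumerate(protein.residues):
        pc = res.atom_coords()
        dmin = np.min(np.linalg.norm(pc[:, None, :] - dna_atoms[None, :, :], axis=-1))
        y[k] = 1 if dmin < cutoff else 0
    return y


def build_graph(structure: ResidueStructure,
                dna_atoms: np.ndarray | None = None,
                contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                label_cutoff: float = DEFAULT_LABEL_CUTOFF,
                node_coord: str = "CA",
                X: np.ndarray | None = None,
                name: str = "") -> ProteinGraph:
    """Assemble the full residue graph for one chain.

    node_coord selects the per-node coordinate for the equivariant branch:
    "CA" (default) or "centroid" (side-chain centroid).
    """
    centroids = np.array([side_chain_centroid(r) for r in structure.residues])
    if node_coord == "CA":
        coords = np.array([
            (r.get_atom("CA").xyz if r.get_atom("CA") is not None else centroids[k])
            for k, r in enumerate(structure.residues)
        ], dtype=np.float64)
    elif node_coord == "centroid":
        coords = centroids
    else:
        raise ValueError(f"unknown node_coord: {node_coord!r}")

    A = build_adjacency(centroids, cutoff=contact_cutoff)
    edge_index = edges_from_adjacency(A)
    E = compute_edge_features(coords, edge_index,
                              orientations=residue_orientations(structure))
    y = None
    if dna_atoms is not None:
        y = label_binding_sites(structure, dna_atoms, cutoff=label_cutoff)
    return ProteinGraph(X=X, A=A, coords=coords, edge_index=edge_index,
                        E=E, y=y, name=name or structure.chain_id,
                        sequence=structure.sequence)
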