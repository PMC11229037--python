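"""Self-contained synthetic inputs: toy structures, feature blocks, corpora.

Real inputs to this pipeline (crystal structures, PSI-BLAST/HHsuite profiles,
language-model embeddings) are large and externally computed; these
generators emulate their shapes and the geometric/statistical couplings the
method exploits, so the full pipeline is exercisable offline:

* ``make_structure`` places residues on an ideal alpha-helix (rise 1.5 Å,
  100 degree turn, radius 2.3 Å) with backbone plus pseudo-side-chain atoms,
  and scatters DNA pseudo-atoms inside a binding pocket.
* ``make_feature_blocks`` draws all eight node-feature blocks at their
  declared widths from a standard normal, then shifts pocket residues by a
  class-conditional mean along a fixed random direction — a learnable but
  noisy signal whose strength is the ``feature_signal_strength`` dial.
* ``make_corpus`` composes structures, graphs, features and labels into a
  labelled corpus with a requested positive fraction (default 0.1, matching
  the benchmark-scale binding/nonbinding imbalance).

Everything is deterministic given the seed.  Toy PSI-BLAST and HHsuite
profile writers are included so the text readers can be tested round-trip;
the files they produce are synthetic and follow only the layout of the real
formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import (AMINO_ACIDS, BLOCK_ORDER, BLOCK_WIDTHS, FeatureBlock,
                       assemble_node_features, one_hot)
from .structure import (Atom, ProteinGraph, Residue, ResidueStructure,
                        build_graph, label_binding_sites)

__all__ = ["FixtureSpec", "make_structure", "make_feature_blocks",
           "make_corpus", "write_synthetic_pssm", "write_synthetic_hhm"]

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TURN = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureSpec:
    n_residues: int = 100
    seed: int = 0
    pocket_center: np.ndarray | None = None  # default: near a random residue
    pocket_radius: float = 3.0  # Å scatter of the DNA pseudo-atoms
    feature_signal_strength: float = 1.75
    n_dna_atoms: int = 20
    positive_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.pocket_radius <= 0:
            raise ValueError("pocket_radius must be positive")


def helix_ca(i: int | np.ndarray) -> np.ndarray:
    """Ideal-helix CA coordinate(s) for residue index i (0-based)."""
    theta = np.deg2rad(HELIX_TURN) * np.asarray(i, dtype=np.float64)
    return np.stack([HELIX_RADIUS * np.cos(theta),
                     HELIX_RADIUS * np.sin(theta),
                     HELIX_RISE * np.asarray(i, dtype=np.float64)], axis=-1)


def make_structure(spec: FixtureSpec) -> tuple[ResidueStructure, np.ndarray]:
    """A toy helical chain plus DNA pseudo-atoms near the pocket center."""
    rng = np.random.default_rng(spec.seed)
    letters = rng.choice(list(AMINO_ACIDS), size=spec.n_residues)
    residues: list[Residue] = []
    for i in range(spec.n_residues):
        ca = helix_ca(i)
        radial = np.array([np.cos(np.deg2rad(HELIX_TURN) * i),
                           np.sin(np.deg2rad(HELIX_TURN) * i), 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        atoms = [
            Atom("N", "N", ca - 0.6 * radial - 0.9 * axis),
            Atom("CA", "C", ca.copy()),
            Atom("C", "C", ca + 0.5 * radial + 0.9 * axis),
            Atom("O", "O", ca + 1.2 * radial + 1.4 * axis),
        ]
        letter = str(letters[i])
        if letter != "G":  # glycine: backbone only
            n_side = int(rng.integers(1, 5))
            for s in range(1, n_side + 1):
                pos = ca + (1.0 + 1.4 * s) * radial + rng.normal(0, 0.15, 3)
                atoms.append(Atom(f"C{'BGDE'[s - 1]}", "C", pos))
        residues.append(Residue(res_name=_THREE_LETTER[letter],
                                res_index=i + 1, atoms=atoms))
    structure = ResidueStructure(chain_id="A", residues=residues)

    if spec.pocket_center is not None:
        center = np.asarray(spec.pocket_center, dtype=np.float64)
    else:
        # anchor the pocket just outside a random residue so structure alone
        # does not reveal which part of the chain binds
        anchor = int(rng.integers(0, spec.n_residues))
        center = helix_ca(anchor) * np.array([1.9, 1.9, 1.0])
    # uniform scatter in the pocket ball
    direction = rng.normal(size=(spec.n_dna_atoms, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = spec.pocket_radius * rng.random(spec.n_dna_atoms) ** (1 / 3)
    dna_atoms = center + direction * radius[:, None]
    return structure, dna_atoms


def _pocket_labels(structure: ResidueStructure, dna_atoms: np.ndarray,
                   fraction: float) -> tuple[np.ndarray, float]:
    """Labels at the distance cutoff whose positive count matches `fraction`.

    The per-residue minimum atomic distance to the DNA cloud is computed
    once; the cutoff is placed just above the k-th smallest distance with
    k = round(fraction * L), then labels come from label_binding_sites at
    that cutoff, keeping the labelling rule identical to the real pipeline.
    """
    dmin = np.array([
        np.min(np.linalg.norm(res.atom_coords()[:, None, :]
                              - dna_atoms[None, :, :], axis=-1))
        for res in structure.residues
    ])
    k = max(1, int(round(fraction * len(structure))))
    k = min(k, len(structure) - 1) if len(structure) > 1 else 1
    cutoff = float(np.sort(dmin)[k - 1]) + 1e-6
    return label_binding_sites(structure, dna_atoms, cutoff=cutoff), cutoff


def signal_directions(seed: int) -> dict[str, np.ndarray]:
    """One fixed random unit direction per feature block.

    The class-conditional mean shift is applied along these directions; a
    corpus shares one set so the binding signal is learnable across
    proteins, not merely within one.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in BLOCK_ORDER:
        d = rng.normal(size=BLOCK_WIDTHS[name])
        out[name] = d / np.linalg.norm(d)
    return out


def make_feature_blocks(spec: FixtureSpec, L: int,
                        labels: np.ndarray | None = None,
                        sequence: str | None = None,
                        rng: np.random.Generator | None = None,
                        directions: dict[str, np.ndarray] | None = None,
                        ) -> dict[str, FeatureBlock]:
    """All eight feature blocks at their declared widths.

    Blocks are standard normal; residues labelled 1 receive an additional
    mean shift of feature_signal_strength along a fixed random unit
    direction per block (shared corpus-wide when `directions` is supplied).
    The OneHot block is the true encoding when a sequence is given.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if directions is None:
        directions = signal_directions(spec.seed)
    labels = np.zeros(L, dtype=np.int8) if labels is None else np.asarray(labels)
    blocks: dict[str, FeatureBlock] = {}
    for name in BLOCK_ORDER:
        width = BLOCK_WIDTHS[name]
        if name == "OneHot" and sequence is not None:
            blocks[name] = one_hot(sequence)
            continue
        matrix = rng.normal(size=(L, width))
        matrix += (spec.feature_signal_strength * labels[:, None]
                   * directions[name][None, :])
        blocks[name] = FeatureBlock(name, matrix)
    return blocks


def make_protein(spec: FixtureSpec, name: str = "synthetic",
                 directions: dict[str, np.ndarray] | None = None) -> ProteinGraph:
    """One fully assembled labelled protein graph."""
    structure, dna_atoms = make_structure(spec)
    y, cutoff = _pocket_labels(structure, dna_atoms, spec.positive_fraction)
    rng = np.random.default_rng(spec.seed + 7)
    blocks = make_feature_blocks(spec, len(structure), labels=y,
                                 sequence=structure.sequence, rng=rng,
                                 directions=directions)
    X = assemble_node_features(blocks)
    graph = build_graph(structure, dna_atoms=dna_atoms, label_cutoff=cutoff,
                        X=X, name=name)
    return graph


def make_corpus(n_proteins: int, spec: FixtureSpec | None = None
                ) -> list[ProteinGraph]:
    """A labelled corpus of synthetic proteins, deterministic given the seed."""
    spec = spec or FixtureSpec()
    master = np.random.default_rng(spec.seed)
    directions = signal_directions(spec.seed + 13)
    graphs: list[ProteinGraph] = []
    for p in range(n_proteins):
        sub_seed = int(master.integers(0, 2**31 - 1))
        n_res = int(master.integers(max(10, spec.n_residues - 10),
                                    spec.n_residues + 11))
        sub = FixtureSpec(
            n_residues=n_res, seed=sub_seed,
            pocket_radius=spec.pocket_radius,
            feature_signal_strength=spec.feature_signal_strength,
            n_dna_atoms=spec.n_dna_atoms,
            positive_fraction=spec.positive_fraction,
        )
        graphs.append(make_protein(sub, name=f"syn{p:03d}", directions=directions))
    return graphs


# -- synthetic profile files (layout-only emulations of the real formats) ----

def write_synthetic_pssm(path: str | Path, scores: np.ndarray,
                         sequence: str) -> None:
    """Write a toy PSI-BLAST ASCII PSSM holding the given [L, 20] raw scores."""
    scores = np.asarray(scores)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS),
    ]
    for i, (aa, row) in enumerate(zip(sequence, scores), start=1):
        svals = " ".join(f"{int(v):3d}" for v in row)
        pvals = " ".join("  0" for _ in row)
        lines.append(f"{i:5d} {aa}  {svals}  {pvals}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    Path(path).write_text("\n".join(lines))


def write_synthetic_hhm(path: str | Path, emissions: np.ndarray,
                        transitions: np.ndarray, sequence: str) -> None:
    """Write a toy HHsuite .hhm file from stored integer values.

    `emissions` is [L, 20] and `transitions` [L, 10]; entries are the raw
    integers of the format (probability = 2^(-v/1000)) or -1 for '*'.
    """
    def fmt(v) -> str:
        return "*" if v < 0 else str(int(v))

    lines = [
        "HHsearch 1.5",
        "NAME  synthetic",
        f"LENG  {len(sequence)} match states",
        "#",
        "NULL   3706 5728 4211 4064 4839 3729 4763 4308 4069 3323 "
        "5509 4640 4464 4937 4285 4423 3815 3783 6325 4665",
        "HMM    A\tC\tD\tE\tF\tG\tH\tI\tK\tL\tM\tN\tP\tQ\tR\tS\tT\tV\tW\tY",
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(sequence):
        em = "\t".join(fmt(v) for v in emissions[i])
        tr = "\t".join(fmt(v) for v in transitions[i])
        lines.append(f"{aa} {i + 1}\t{em}\t{i + 1}")
        lines.append(f"       {tr}")
        lines.append("")
    lines.append("//")
    Path(path).write_text("\n".join(lines))
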