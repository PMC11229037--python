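"""Node-feature blocks and their assembly into the 6524-dim residue matrix.

Eight per-residue blocks are concatenated in a fixed order:

=========  =====  ==============================================
block      width  content
=========  =====  ==============================================
PSSM          20  logistic-normalized PSI-BLAST profile scores
HMM           30  HHsuite .hhm profile, 2^(-v/1000) decoded
OneHot        20  residue-type indicator (X -> zero row)
Atomic         7  per-residue atomic features (precomputed)
SS            14  secondary-structure profile (precomputed)
MSA          256  alignment-derived embedding (precomputed)
ESM2        5153  protein-language-model embedding (precomputed)
ProtTrans   1024  protein-language-model embedding (precomputed)
=========  =====  ==============================================

Total width 6524.  The normalizations for PSSM and HMM follow the
GraphBind-lineage conventions; both are isolated here so an alternative is
a one-line swap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "BLOCK_WIDTHS",
    "BLOCK_ORDER",
    "TOTAL_WIDTH",
    "FeatureBlock",
    "read_pssm",
    "read_hhm",
    "one_hot",
    "load_block",
    "validate_block",
    "assemble_node_features",
    "block_offsets",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BLOCK_WIDTHS: dict[str, int] = {
    "PSSM": 20,
    "HMM": 30,
    "OneHot": 20,
    "Atomic": 7,
    "SS": 14,
    "MSA": 256,
    "ESM2": 5153,
    "ProtTrans": 1024,
}
BLOCK_ORDER: tuple[str, ...] = tuple(BLOCK_WIDTHS)
TOTAL_WIDTH = sum(BLOCK_WIDTHS.values())  # 6524


@dataclass
class FeatureBlock:
    name: str
    matrix: np.ndarray  # [L, d_name]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        validate_block(self.name, self.matrix)

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


def validate_block(name: str, matrix: np.ndarray) -> None:
    if name not in BLOCK_WIDTHS:
        raise ValueError(f"unknown feature block {name!r}; expected one of {BLOCK_ORDER}")
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != BLOCK_WIDTHS[name]:
        raise ValueError(
            f"block {name!r} must have shape [L, {BLOCK_WIDTHS[name]}], "
            f"got {matrix.shape}"
        )
    if not np.isfinite(matrix).all():
        raise ValueError(f"block {name!r} contains non-finite values")


def _logistic(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def read_pssm(path: str | Path, expected_length: int | None = None) -> FeatureBlock:
    """Read a PSI-BLAST ASCII PSSM and logistic-normalize the 20 score columns.

    Each raw log-odds score v is mapped to 1/(1+e^-v), giving values in (0, 1).
    """
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        # profile rows start "<pos> <aa> <20 scores> ..."
        if len(parts) >= 22 and parts[0].isdigit() and parts[1].isalpha() \
                and len(parts[1]) == 1:
            rows.append([float(x) for x in parts[2:22]])
    if not rows:
        raise ValueError(f"no PSSM profile rows found in {path}")
    scores = np.asarray(rows, dtype=np.float64)
    if expected_length is not None and scores.shape[0] != expected_length:
        raise ValueError(
            f"PSSM has {scores.shape[0]} positions, sequence has {expected_length}"
        )
    return FeatureBlock("PSSM", _logistic(scores))


def decode_hhm_value(token: str) -> float:
    """Decode one stored .hhm integer: p = 2^(-v/1000); '*' means p = 0."""
    if token == "*":
        return 0.0
    return float(2.0 ** (-int(token) / 1000.0))


def read_hhm(path: str | Path, expected_length: int | None = None) -> FeatureBlock:
    """Read an HHsuite .hhm profile into an [L, 30] block.

    Each residue contributes 20 match-emission probabilities followed by the
    10 transition/diversity values of the second profile line, all decoded
    via 2^(-v/1000) with '*' mapping to 0.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("HMM"))
    except StopIteration:
        raise ValueError(f"no HMM block found in {path}") from None

    rows: list[list[float]] = []
    i = start + 3  # skip the two header lines and the null-transition line
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("//") or not line:
            i += 1
            continue
        parts = line.split()
        if len(parts) < 22 or len(parts[0]) != 1 or not parts[0].isalpha():
            i += 1
            continue
        try:
            emissions = [decode_hhm_value(t) for t in parts[2:22]]
        except ValueError:
            raise ValueError(f"malformed emission line {i + 1} in {path}") from None
        if i + 1 >= len(lines):
            raise ValueError(f"truncated transition line after line {i + 1} in {path}")
        trans_parts = lines[i + 1].split()
        if len(trans_parts) < 10:
            raise ValueError(f"malformed transition line {i + 2} in {path}")
        try:
            transitions = [decode_hhm_value(t) for t in trans_parts[:10]]
        except ValueError:
            raise ValueError(f"malformed transition line {i + 2} in {path}") from None
        rows.append(emissions + transitions)
        i += 2
    if not rows:
        raise ValueError(f"no profile rows parsed from {path}")
    matrix = np.asarray(rows, dtype=np.float64)
    if expected_length is not None and matrix.shape[0] != expected_length:
        raise ValueError(
            f"HMM has {matrix.shape[0]} positions, sequence has {expected_length}"
        )
    return FeatureBlock("HMM", matrix)


def one_hot(sequence: str) -> FeatureBlock:
    """Indicator encoding over the 20 standard residues; X gives a zero row."""
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    out = np.zeros((len(sequence), 20), dtype=np.float64)
    for i, aa in enumerate(sequence.upper()):
        if aa == "X":
            continue
        if aa not in index:
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")
        out[i, index[aa]] = 1.0
    return FeatureBlock("OneHot", out)


def load_block(path: str | Path, name: str) -> FeatureBlock:
    """Load a precomputed dense block (delimited text or HDF5) and validate it."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            matrix = np.asarray(f["data"])
    else:
        matrix = np.loadtxt(path, ndmin=2)
    return FeatureBlock(name, matrix)


def block_offsets() -> dict[str, tuple[int, int]]:
    """Column slice (start, stop) of each block inside the assembled matrix."""
    out: dict[str, tuple[int, int]] = {}
    start = 0
    for name in BLOCK_ORDER:
        out[name] = (start, start + BLOCK_WIDTHS[name])
        start += BLOCK_WIDTHS[name]
    return out


def assemble_node_features(blocks: dict[str, FeatureBlock] | list[FeatureBlock]) -> np.ndarray:
    """Concatenate all eight blocks in the fixed order into an [L, 6524] matrix."""
    if not isinstance(blocks, dict):
        blocks = {b.name: b for b in blocks}
    missing = [n for n in BLOCK_ORDER if n not in blocks]
    if missing:
        raise ValueError(f"missing feature blocks: {missing}")
    lengths = {n: blocks[n].L for n in BLOCK_ORDER}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"inconsistent block lengths: {lengths}")
    X = np.concatenate([blocks[n].matrix for n in BLOCK_ORDER], axis=1)
    assert X.shape[1] == TOTAL_WIDTH
    return X
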