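"""Read profile files and assemble the 6524-dimensional node-feature matrix.

Generates toy PSI-BLAST and HHsuite profile files for a 5-residue peptide,
reads them back through the normalizing readers, fills the remaining blocks
with synthetic tables, and concatenates everything.
"""

import tempfile
from pathlib import Path

import numpy as np

from egpdi import (BLOCK_WIDTHS, FeatureBlock, assemble_node_features,
                   block_offsets, one_hot, read_hhm, read_pssm)
from egpdi.synthetic import write_synthetic_hhm, write_synthetic_pssm

SEQ = "ACDEF"
rng = np.random.default_rng(0)

with tempfile.TemporaryDirectory() as tmp:
    pssm_path = Path(tmp) / "toy.pssm"
    hhm_path = Path(tmp) / "toy.hhm"
    write_synthetic_pssm(pssm_path, rng.integers(-10, 11, size=(5, 20)), SEQ)
    write_synthetic_hhm(hhm_path, rng.integers(0, 5000, size=(5, 20)),
                        rng.integers(0, 5000, size=(5, 10)), SEQ)

    blocks = {
        "PSSM": read_pssm(pssm_path, expected_length=5),
        "HMM": read_hhm(hhm_path, expected_length=5),
        "OneHot": one_hot(SEQ),
    }
    for name in ("Atomic", "SS", "MSA", "ESM2", "ProtTrans"):
        blocks[name] = FeatureBlock(name, rng.normal(size=(5, BLOCK_WIDTHS[name])))

X = assemble_node_features(blocks)
print(f"assembled node features: {X.shape[0]} residues x {X.shape[1]} dims")
print(f"PSSM values lie in (0,1) after logistic normalization: "
      f"[{X[:, :20].min():.3f}, {X[:, :20].max():.3f}]")
print(f"HMM values lie in [0,1] after 2^(-v/1000) decoding:    "
      f"[{X[:, 20:50].min():.3f}, {X[:, 20:50].max():.3f}]")
print("block column offsets:", block_offsets())
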