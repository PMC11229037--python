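import numpy as np
import pytest

from egpdi.egnn import EgnnConfig, EgnnEncoder
from egpdi.gcnii import GcniiConfig, GcniiEncoder
from egpdi.structure import ProteinGraph, build_adjacency, compute_edge_features
from egpdi.structure import edges_from_adjacency


def make_pdb_text(records):
    """Minimal PDB writer for test fixtures.

    records: list of (serial, name, altloc, resn, chain, resseq, xyz, occ, elem)
    """
    lines = []
    for serial, name, altloc, resn, chain, resseq, xyz, occ, elem in records:
        field = name if len(name) == 4 else f" {name:<3}"
        lines.append(
            f"ATOM  {serial:>5} {field}{altloc}{resn:>3} {chain}{resseq:>4} "
            f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_writer(tmp_path):
    def write(records, fname="test.pdb"):
        path = tmp_path / fname
        path.write_text(make_pdb_text(records))
        return path

    return write


def random_graph(rng, n_nodes, d_x=24, cutoff=6.0, coord_scale=3.0):
    """A small random ProteinGraph for encoder tests."""
    coords = rng.normal(scale=coord_scale, size=(n_nodes, 3))
    A = build_adjacency(coords, cutoff=cutoff)
    edge_index = edges_from_adjacency(A)
    orient = rng.normal(size=(n_nodes, 3))
    E = compute_edge_features(coords, edge_index, orientations=orient)
    X = rng.normal(size=(n_nodes, d_x))
    return ProteinGraph(X=X, A=A, coords=coords, edge_index=edge_index, E=E)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_egnn(rng):
    config = EgnnConfig(n_layers=2, hidden_dim=6, mlp_width=5, input_dim=24)
    return EgnnEncoder(config, rng)


@pytest.fixture
def tiny_gcnii(rng):
    config = GcniiConfig(n_layers=4, hidden_dim=6, input_dim=24)
    return GcniiEncoder(config, rng)


def random_rigid_transform(rng, allow_reflection=True):
    """Random orthogonal matrix (optionally improper) and translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if not allow_reflection and np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t
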