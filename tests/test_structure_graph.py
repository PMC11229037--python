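"""Structure parsing and residue-graph construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egpdi.structure import (Atom, Residue, ResidueStructure, build_adjacency,
                             build_graph, compute_edge_features,
                             label_binding_sites, parse_structure,
                             side_chain_centroid)
from egpdi.structure import edges_from_adjacency

from conftest import random_rigid_transform


def residue(name="ALA", index=1, atoms=()):
    return Residue(res_name=name, res_index=index, atoms=list(atoms))


class TestParseStructure:
    def test_single_residue_with_five_atoms(self, pdb_writer):
        records = [
            (1, "N", " ", "ALA", "A", 1, (0.0, 0.0, 0.0), 1.0, "N"),
            (2, "CA", " ", "ALA", "A", 1, (1.5, 0.0, 0.0), 1.0, "C"),
            (3, "C", " ", "ALA", "A", 1, (2.0, 1.0, 0.0), 1.0, "C"),
            (4, "O", " ", "ALA", "A", 1, (3.0, 1.5, 0.0), 1.0, "O"),
            (5, "CB", " ", "ALA", "A", 1, (1.5, -1.5, 0.0), 1.0, "C"),
        ]
        s = parse_structure(pdb_writer(records), "A")
        assert len(s) == 1
        assert len(s.residues[0].atoms) == 5
        assert s.residues[0].res_name == "ALA"

    def test_chain_filter_keeps_requested_chain_only(self, pdb_writer):
        records = [
            (1, "CA", " ", "GLY", "A", 1, (0.0, 0.0, 0.0), 1.0, "C"),
            (2, "CA", " ", "GLY", "A", 2, (3.8, 0.0, 0.0), 1.0, "C"),
            (3, "CA", " ", "ALA", "B", 1, (50.0, 0.0, 0.0), 1.0, "C"),
        ]
        s = parse_structure(pdb_writer(records), "A")
        assert len(s) == 2
        assert all(r.res_name == "GLY" for r in s.residues)

    def test_highest_occupancy_altloc_kept(self, pdb_writer):
        records = [
            (1, "CA", "A", "SER", "A", 1, (0.0, 0.0, 0.0), 0.6, "C"),
            (2, "CA", "B", "SER", "A", 1, (9.0, 9.0, 9.0), 0.4, "C"),
            (3, "CB", " ", "SER", "A", 1, (1.0, 1.0, 1.0), 1.0, "C"),
        ]
        s = parse_structure(pdb_writer(records), "A")
        ca = s.residues[0].get_atom("CA")
        np.testing.assert_allclose(ca.xyz, [0.0, 0.0, 0.0])
        assert ca.occupancy == pytest.approx(0.6)

    def test_missing_chain_raises(self, pdb_writer):
        records = [(1, "CA", " ", "GLY", "A", 1, (0.0, 0.0, 0.0), 1.0, "C")]
        with pytest.raises(ValueError, match="chain not found"):
            parse_structure(pdb_writer(records), "Z")

    def test_hetatm_only_chain_raises(self, pdb_writer, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        with pytest.raises(ValueError, match="no standard protein residues"):
            parse_structure(path, "A")


class TestSideChainCentroid:
    def test_midpoint_of_two_side_chain_atoms(self):
        r = residue(atoms=[
            Atom("CA", "C", np.array([9.0, 9.0, 9.0])),
            Atom("CB", "C", np.array([0.0, 0.0, 0.0])),
            Atom("CG", "C", np.array([2.0, 0.0, 0.0])),
        ])
        np.testing.assert_allclose(side_chain_centroid(r), [1.0, 0.0, 0.0])

    def test_glycine_falls_back_to_ca(self):
        r = residue(name="GLY", atoms=[
            Atom("N", "N", np.array([0.0, 1.0, 0.0])),
            Atom("CA", "C", np.array([1.0, 2.0, 3.0])),
            Atom("C", "C", np.array([2.0, 2.0, 2.0])),
            Atom("O", "O", np.array([3.0, 2.0, 2.0])),
        ])
        np.testing.assert_allclose(side_chain_centroid(r), [1.0, 2.0, 3.0])

    def test_mean_matches_per_axis_brute_force(self, rng):
        coords = rng.normal(size=(3, 3))
        r = residue(atoms=[Atom(n, "C", coords[k])
                           for k, n in enumerate(["CB", "CG", "CD"])])
        expected = np.array([np.mean([c[axis] for c in coords])
                             for axis in range(3)])
        np.testing.assert_allclose(side_chain_centroid(r), expected)

    def test_hydrogens_excluded(self):
        r = residue(atoms=[
            Atom("CB", "C", np.array([1.0, 0.0, 0.0])),
            Atom("HB1", "H", np.array([100.0, 0.0, 0.0])),
        ])
        np.testing.assert_allclose(side_chain_centroid(r), [1.0, 0.0, 0.0])


class TestBuildAdjacency:
    def test_strict_inequality_at_cutoff(self):
        below = np.array([[0.0, 0, 0], [16.999, 0, 0]])
        at = np.array([[0.0, 0, 0], [17.0, 0, 0]])
        assert build_adjacency(below)[0, 1] == 1
        assert build_adjacency(at)[0, 1] == 0

    def test_single_node_gives_zero_matrix(self):
        A = build_adjacency(np.zeros((1, 3)))
        assert A.shape == (1, 1) and A[0, 0] == 0

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(-30, 30, size=(50, 3))
        A = build_adjacency(pts, cutoff=17.0)
        for i in range(50):
            for j in range(50):
                expected = int(i != j and
                               np.linalg.norm(pts[i] - pts[j]) < 17.0)
                assert A[i, j] == expected

    def test_nonfinite_coordinates_rejected(self):
        pts = np.array([[0.0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            build_adjacency(pts)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(1, 100), st.integers(0, 10_000))
    def test_symmetry_and_zero_diagonal(self, n, seed):
        pts = np.random.default_rng(seed).uniform(-40, 40, size=(n, 3))
        A = build_adjacency(pts)
        assert (A == A.T).all()
        assert np.diag(A).sum() == 0

    def test_edge_set_invariant_under_rigid_transform(self, rng):
        pts = rng.uniform(-20, 20, size=(30, 3))
        A = build_adjacency(pts)
        for _ in range(20):
            Q, t = random_rigid_transform(rng)
            np.testing.assert_array_equal(build_adjacency(pts @ Q.T + t), A)


class TestEdgeFeatures:
    def test_distance_three_four_five(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        E = compute_edge_features(coords, np.array([[0, 1]]))
        assert E[0, 0] == pytest.approx(5.0)

    def test_parallel_and_antiparallel_cosines(self):
        coords = np.zeros((2, 3))
        par = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        anti = np.array([[1.0, 0, 0], [-3.0, 0, 0]])
        ei = np.array([[0, 1]])
        assert compute_edge_features(coords, ei, par)[0, 1] == pytest.approx(1.0)
        assert compute_edge_features(coords, ei, anti)[0, 1] == pytest.approx(-1.0)

    def test_degenerate_orientation_gives_zero_cosine(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        orient = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        E = compute_edge_features(coords, np.array([[0, 1]]), orient)
        assert E[0, 1] == 0.0

    def test_matches_scalar_loop_oracle(self, rng):
        coords = rng.normal(scale=5, size=(12, 3))
        orient = rng.normal(size=(12, 3))
        A = build_adjacency(coords, cutoff=8.0)
        ei = edges_from_adjacency(A)
        E = compute_edge_features(coords, ei, orient)
        for k, (i, j) in enumerate(ei):
            d = np.sqrt(sum((coords[i, a] - coords[j, a]) ** 2 for a in range(3)))
            cos = (np.dot(orient[i], orient[j])
                   / (np.linalg.norm(orient[i]) * np.linalg.norm(orient[j])))
            assert E[k, 0] == pytest.approx(d, abs=1e-12)
            assert E[k, 1] == pytest.approx(cos, abs=1e-12)
        assert (E[:, 0] >= 0).all()
        assert (np.abs(E[:, 1]) <= 1).all()


class TestBindingLabels:
    def _protein(self, ca_positions):
        residues = [residue(index=k + 1,
                            atoms=[Atom("CA", "C", np.asarray(p, dtype=float))])
                    for k, p in enumerate(ca_positions)]
        return ResidueStructure(chain_id="A", residues=residues)

    def test_atom_below_cutoff_labelled_positive(self):
        p = self._protein([[0, 0, 0]])
        y = label_binding_sites(p, np.array([[0.4, 0, 0]]), cutoff=0.5)
        assert y.tolist() == [1]

    def test_all_far_gives_zero_labels(self):
        p = self._protein([[0, 0, 0], [10, 0, 0]])
        y = label_binding_sites(p, np.array([[50.0, 0, 0]]), cutoff=0.5)
        assert y.tolist() == [0, 0]

    def test_matches_exhaustive_all_pairs_scan(self, rng):
        ca = rng.normal(scale=6, size=(10, 3))
        p = self._protein(ca)
        dna = rng.normal(scale=6, size=(20, 3))
        cutoff = 4.0
        y = label_binding_sites(p, dna, cutoff=cutoff)
        for i in range(10):
            dmin = min(np.linalg.norm(ca[i] - dna[b]) for b in range(20))
            assert y[i] == int(dmin < cutoff)

    def test_empty_dna_rejected(self):
        p = self._protein([[0, 0, 0]])
        with pytest.raises(ValueError, match="empty DNA"):
            label_binding_sites(p, np.zeros((0, 3)))


def test_build_graph_end_to_end_invariants(pdb_writer, rng):
    records = []
    serial = 1
    for k in range(6):
        base = np.array([k * 3.8, 0.0, 0.0])
        for name, off, elem in [("N", (-0.5, -0.9, 0), "N"), ("CA", (0, 0, 0), "C"),
                                ("C", (0.5, 0.9, 0), "C"), ("CB", (0, -1.5, 0.4), "C")]:
            records.append((serial, name, " ", "ALA", "A", k + 1,
                            tuple(base + np.array(off)), 1.0, elem))
            serial += 1
    s = parse_structure(pdb_writer(records), "A")
    g = build_graph(s, dna_atoms=np.array([[0.0, -1.5, 0.6]]), label_cutoff=1.0)
    assert g.n_residues == 6
    assert (g.A == g.A.T).all() and np.diag(g.A).sum() == 0
    assert len(g.edge_index) == np.triu(g.A, 1).sum()
    assert g.E.shape == (len(g.edge_index), 2)
    assert g.y[0] == 1 and g.y[-1] == 0
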