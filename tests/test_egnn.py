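"""Equivariant branch: EGCL message passing, coordinate updates, the
residual/identity node update, and the E(3)/permutation symmetries."""

import math

import numpy as np
import pytest

from egpdi.autodiff import Tensor, concat
from egpdi.egnn import EgclLayer, EgnnConfig, EgnnEncoder, directed_edges
from egpdi.nn import beta_schedule

from conftest import random_graph, random_rigid_transform
from oracles import egnn_layer_dense, mlp_eval


class TestBetaSchedule:
    def test_log_of_e_is_one(self):
        assert beta_schedule(math.e - 1.0, 1) == pytest.approx(1.0)

    def test_strictly_decreasing_and_vanishing(self):
        values = [beta_schedule(0.5, l) for l in range(1, 60)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert beta_schedule(0.5, 10_000) < 1e-4

    def test_grid_matches_scalar_evaluation(self):
        for l in range(1, 9):
            assert beta_schedule(0.5, l) == pytest.approx(math.log(0.5 / l + 1))

    def test_invalid_layer_or_lambda_rejected(self):
        with pytest.raises(ValueError):
            beta_schedule(0.5, 0)
        with pytest.raises(ValueError):
            beta_schedule(0.0, 1)


class TestEdgeMessage:
    def test_coincident_points_give_zero_squared_distance_input(self, rng):
        config = EgnnConfig(n_layers=1, hidden_dim=4, mlp_width=4, input_dim=4)
        layer = EgclLayer(config, rng)
        h = Tensor(rng.normal(size=(2, 4)))
        x_same = Tensor(np.ones((2, 3)))
        e = Tensor(np.zeros((1, 2)))
        m = layer.edge_message(h.take_rows([0]), h.take_rows([1]),
                               x_same.take_rows([0]), x_same.take_rows([1]), e)
        inp = np.concatenate([h.data[0], h.data[1], [0.0], [0.0, 0.0]])
        np.testing.assert_allclose(m.data[0], mlp_eval(inp[None, :], layer.phi_e)[0],
                                   rtol=1e-12)

    def test_two_node_message_matches_hand_unrolled_mlp(self, rng):
        config = EgnnConfig(n_layers=1, hidden_dim=3, mlp_width=4, input_dim=3)
        layer = EgclLayer(config, rng)
        h = rng.normal(size=(2, 3))
        x = rng.normal(size=(2, 3))
        e = rng.normal(size=(1, 2))
        m = layer.edge_message(Tensor(h[[0]]), Tensor(h[[1]]),
                               Tensor(x[[0]]), Tensor(x[[1]]), Tensor(e))
        sq = np.sum((x[0] - x[1]) ** 2) / config.dist_scale ** 2
        inp = np.concatenate([h[0], h[1], [sq], e[0]])[None, :]
        z1 = inp @ layer.phi_e.fc1.W.data + layer.phi_e.fc1.b.data
        a1 = z1 / (1 + np.exp(-z1))
        z2 = a1 @ layer.phi_e.fc2.W.data + layer.phi_e.fc2.b.data
        expected = z2 / (1 + np.exp(-z2))
        np.testing.assert_allclose(m.data, expected, rtol=1e-12)

    def test_message_is_direction_sensitive(self, rng):
        config = EgnnConfig(n_layers=1, hidden_dim=3, mlp_width=4, input_dim=3)
        layer = EgclLayer(config, rng)
        h = Tensor(rng.normal(size=(2, 3)))
        x = Tensor(rng.normal(size=(2, 3)))
        e = Tensor(rng.normal(size=(1, 2)))
        m_ij = layer.edge_message(h.take_rows([0]), h.take_rows([1]),
                                  x.take_rows([0]), x.take_rows([1]), e)
        m_ji = layer.edge_message(h.take_rows([1]), h.take_rows([0]),
                                  x.take_rows([1]), x.take_rows([0]), e)
        assert not np.allclose(m_ij.data, m_ji.data)


class TestCoordinateUpdate:
    def test_normalization_constant_for_two_nodes_is_one(self, rng):
        config = EgnnConfig(n_layers=1, hidden_dim=3, mlp_width=3, input_dim=3)
        layer = EgclLayer(config, rng)
        layer.phi_x.fc2.W.data[:] = rng.normal(size=layer.phi_x.fc2.W.shape)
        x = Tensor(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        xi, xj = x.take_rows([0, 1]), x.take_rows([1, 0])
        m = Tensor(rng.normal(size=(2, 3)))
        out = layer.coordinate_update(x, xi, xj, m, np.array([0, 1]), 2)
        phi = mlp_eval(m.data, layer.phi_x)
        expected = x.data + np.array([(x.data[0] - x.data[1]) * phi[0, 0],
                                      (x.data[1] - x.data[0]) * phi[1, 0]])
        np.testing.assert_allclose(out.data, expected, rtol=1e-12)

    def test_zero_phi_x_leaves_coordinates_unchanged(self, rng):
        config = EgnnConfig(n_layers=1, hidden_dim=3, mlp_width=3, input_dim=3)
        layer = EgclLayer(config, rng)
        layer.phi_x.fc2.W.data[:] = 0.0
        layer.phi_x.fc2.b.data[:] = 0.0
        g = random_graph(rng, 5, d_x=3)
        ei, ea = directed_edges(g.edge_index, g.E)
        x = Tensor(g.coords)
        h = Tensor(rng.normal(size=(5, 3)))
        m = layer.edge_message(h.take_rows(ei[:, 0]), h.take_rows(ei[:, 1]),
                               x.take_rows(ei[:, 0]), x.take_rows(ei[:, 1]),
                               Tensor(ea))
        out = layer.coordinate_update(x, x.take_rows(ei[:, 0]),
                                      x.take_rows(ei[:, 1]), m, ei[:, 0], 5)
        np.testing.assert_allclose(out.data, g.coords)

    def test_single_node_skips_update(self, rng):
        config = EgnnConfig(n_layers=2, hidden_dim=4, mlp_width=4, input_dim=8)
        enc = EgnnEncoder(config, rng)
        g = random_graph(rng, 1, d_x=8)
        h, trace = enc.forward(g.X, g.A, g.coords, g.edge_index, g.E,
                               return_coords=True)
        assert h.shape == (1, 4)
        for x in trace:
            np.testing.assert_allclose(x, g.coords)


class TestLayerOracle:
    @pytest.mark.parametrize("n_nodes", [2, 4, 6])
    def test_single_layer_matches_explicit_loop_oracle(self, rng, n_nodes):
        config = EgnnConfig(n_layers=1, hidden_dim=5, mlp_width=4,
                            alpha=0.1, lam=0.5, input_dim=5)
        layer = EgclLayer(config, rng)
        layer.phi_x.fc2.W.data[:] = rng.normal(size=layer.phi_x.fc2.W.shape)
        g = random_graph(rng, n_nodes, d_x=5, cutoff=8.0)
        h0 = rng.normal(size=(n_nodes, 5))
        from egpdi.nn import normalize_adjacency

        ei, ea = directed_edges(g.edge_index, g.E)
        h_new, x_new = layer.forward(Tensor(h0), Tensor(g.coords), Tensor(h0),
                                     Tensor(normalize_adjacency(g.A)), ei, ea, 1)
        h_exp, x_exp = egnn_layer_dense(h0, g.coords, h0, g.A, g.edge_index,
                                        g.E, 1, layer, 0.1, 0.5)
        np.testing.assert_allclose(h_new.data, h_exp, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(x_new.data, x_exp, rtol=1e-9, atol=1e-11)

    def test_two_layer_forward_matches_composed_oracle(self, rng):
        config = EgnnConfig(n_layers=2, hidden_dim=4, mlp_width=4,
                            alpha=0.1, lam=0.5, input_dim=7)
        enc = EgnnEncoder(config, rng)
        for lay in enc.layers:
            lay.phi_x.fc2.W.data[:] = rng.normal(size=lay.phi_x.fc2.W.shape)
        g = random_graph(rng, 4, d_x=7, cutoff=8.0)
        h = enc.forward(g.X, g.A, g.coords, g.edge_index, g.E)

        h0 = g.X @ enc.proj.data
        hh, xx = h0.copy(), g.coords.copy()
        for l, layer in enumerate(enc.layers, start=1):
            hh, xx = egnn_layer_dense(hh, xx, h0, g.A, g.edge_index, g.E,
                                      l, layer, 0.1, 0.5)
        np.testing.assert_allclose(h.data, hh, rtol=1e-9, atol=1e-11)


class TestLimits:
    def test_full_initial_residual_ignores_graph_and_messages(self, rng):
        config = EgnnConfig(n_layers=2, hidden_dim=4, mlp_width=4,
                            alpha=1.0, lam=1e-14, input_dim=6)
        enc = EgnnEncoder(config, rng)
        g1 = random_graph(rng, 5, d_x=6, cutoff=8.0)
        g2 = random_graph(rng, 5, d_x=6, cutoff=4.0)
        h1 = enc.forward(g1.X, g1.A, g1.coords, g1.edge_index, g1.E)
        h2 = enc.forward(g1.X, g2.A, g2.coords, g2.edge_index, g2.E)
        h0 = np.maximum(g1.X @ enc.proj.data, 0.0)
        np.testing.assert_allclose(h1.data, h0, rtol=1e-8)
        np.testing.assert_allclose(h1.data, h2.data, rtol=1e-12)

    def test_zero_edge_graph_depends_only_on_node_terms(self, rng):
        config = EgnnConfig(n_layers=2, hidden_dim=4, mlp_width=4, input_dim=6)
        enc = EgnnEncoder(config, rng)
        X = rng.normal(size=(5, 6))
        A = np.zeros((5, 5), dtype=np.int8)
        ei = np.zeros((0, 2), dtype=np.int64)
        E = np.zeros((0, 2))
        h1 = enc.forward(X, A, rng.normal(size=(5, 3)), ei, E)
        h2 = enc.forward(X, A, rng.normal(size=(5, 3)), ei, E)
        np.testing.assert_allclose(h1.data, h2.data)


class TestSymmetries:
    def _encoder_and_graph(self, rng, n=8):
        config = EgnnConfig(n_layers=2, hidden_dim=5, mlp_width=4, input_dim=10)
        enc = EgnnEncoder(config, rng)
        g = random_graph(rng, n, d_x=10, cutoff=7.0)
        return enc, g

    def test_embeddings_invariant_coordinates_equivariant(self, rng):
        enc, g = self._encoder_and_graph(rng)
        h_ref, trace_ref = enc.forward(g.X, g.A, g.coords, g.edge_index, g.E,
                                       return_coords=True)
        for _ in range(100):
            Q, t = random_rigid_transform(rng)
            h_t, trace_t = enc.forward(g.X, g.A, g.coords @ Q.T + t,
                                       g.edge_index, g.E, return_coords=True)
            np.testing.assert_allclose(h_t.data, h_ref.data, rtol=1e-4,
                                       atol=1e-10)
            for x_t, x_ref in zip(trace_t, trace_ref):
                np.testing.assert_allclose(x_t, x_ref @ Q.T + t, rtol=1e-4,
                                           atol=1e-8)

    def test_permutation_equivariance(self, rng):
        enc, g = self._encoder_and_graph(rng)
        perm = rng.permutation(g.n_residues)
        inv = np.argsort(perm)
        Xp = g.X[perm]
        Ap = g.A[np.ix_(perm, perm)]
        coords_p = g.coords[perm]
        ei_p = inv[g.edge_index]
        h = enc.forward(g.X, g.A, g.coords, g.edge_index, g.E)
        hp = enc.forward(Xp, Ap, coords_p, ei_p, g.E)
        np.testing.assert_allclose(hp.data, h.data[perm], rtol=1e-8, atol=1e-10)
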