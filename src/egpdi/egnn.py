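"""E(3)-equivariant branch: stacked EGCL layers with initial residual and
identity mapping.

Each equivariant graph convolution layer (EGCL) passes messages

    m_ij = Phi_e(h_i, h_j, ||x_i - x_j||^2, e_ij)

over the residue contact graph, updates coordinates equivariantly

    x_i' = x_i + 1/(M-1) * sum_{j != i} (x_i - x_j) Phi_x(m_ij)

and aggregates m_i = sum_{j != i} m_ij into a candidate node representation
H~ = Phi_h(h_i, m_i).  That candidate then takes the place of the smoothed
term in the GCNII-style update

    H^(l+1) = sigma( ((1-alpha) P H~ + alpha H^(0)) ((1-beta_l) I + beta_l W^(l)) )

so deep stacks retain part of the original node features.  Because every
geometric quantity entering Phi_e is a squared distance, node embeddings are
invariant — and the internal coordinates equivariant — under any rotation,
translation or reflection of the input coordinates.

Defaults follow the reference configuration: two layers, hidden width 512.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .features import TOTAL_WIDTH
from .nn import MLP, beta_schedule, glorot, normalize_adjacency, residual_identity_update

__all__ = ["EgnnConfig", "EgclLayer", "EgnnEncoder", "directed_edges"]


@dataclass
class EgnnConfig:
    n_layers: int = 2
    hidden_dim: int = 512
    alpha: float = 0.1
    lam: float = 0.5
    mlp_width: int | None = None  # hidden width of Phi_e / Phi_x / Phi_h
    edge_dim: int = 2
    input_dim: int = TOTAL_WIDTH
    dist_scale: float = 17.0  # Å; squared distances enter Phi_e as (d/scale)^2

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if self.mlp_width is None:
            self.mlp_width = self.hidden_dim


def directed_edges(edge_index: np.ndarray,
                   edge_attr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand undirected (i<j) records to both directions for message passing."""
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(-1, 2)
    edge_attr = np.asarray(edge_attr, dtype=np.float64).reshape(-1, edge_attr.shape[-1]) \
        if edge_attr.size else np.zeros((0, 2))
    both = np.concatenate([edge_index, edge_index[:, ::-1]], axis=0)
    attr = np.concatenate([edge_attr, edge_attr], axis=0)
    return both, attr


class EgclLayer:
    """One EGCL with the residual/identity node update."""

    def __init__(self, config: EgnnConfig, rng: np.random.Generator):
        d, w, de = config.hidden_dim, config.mlp_width, config.edge_dim
        self.config = config
        self.phi_e = MLP(rng, 2 * d + 1 + de, w, d, final="silu")
        self.phi_x = MLP(rng, d, w, 1, final="linear")
        # coordinate updates start at the identity: stabilizes early training
        self.phi_x.fc2.W.data[:] = 0.0
        self.phi_h = MLP(rng, 2 * d, w, d, final="linear")
        self.W = glorot(rng, d, d)

    def edge_message(self, h_i: Tensor, h_j: Tensor, x_i: Tensor, x_j: Tensor,
                     e_ij: Tensor) -> Tensor:
        dx = x_i - x_j
        # (d/dist_scale)^2 keeps the geometric input commensurate with h;
        # the fixed rescaling is absorbed into Phi_e's first layer
        sq = (dx * dx).sum(axis=1, keepdims=True) * (1.0 / self.config.dist_scale ** 2)
        return self.phi_e(concat([h_i, h_j, sq, e_ij], axis=1))

    def coordinate_update(self, x: Tensor, x_i: Tensor, x_j: Tensor,
                          m: Tensor, senders: np.ndarray, n_nodes: int) -> Tensor:
        if n_nodes < 2:
            return x  # C = 1/(M-1) undefined; empty sum
        scale = self.phi_x(m)  # [n_edges, 1]
        contrib = (x_i - x_j) * scale
        agg = contrib.scatter_add_rows(senders, n_nodes)
        return x + agg * (1.0 / (n_nodes - 1))

    def node_update(self, h: Tensor, m_i: Tensor, h0: Tensor, P: Tensor,
                    layer: int) -> Tensor:
        h_tilde = self.phi_h(concat([h, m_i], axis=1))
        beta = beta_schedule(self.config.lam, layer)
        return residual_identity_update(h_tilde, h0, P, self.W,
                                        self.config.alpha, beta)

    def forward(self, h: Tensor, x: Tensor, h0: Tensor, P: Tensor,
                edge_index: np.ndarray, edge_attr: np.ndarray,
                layer: int) -> tuple[Tensor, Tensor]:
        n = h.shape[0]
        if len(edge_index):
            senders = edge_index[:, 0]
            receivers = edge_index[:, 1]
            h_i, h_j = h.take_rows(senders), h.take_rows(receivers)
            x_i, x_j = x.take_rows(senders), x.take_rows(receivers)
            m = self.edge_message(h_i, h_j, x_i, x_j, Tensor(edge_attr))
            x_new = self.coordinate_update(x, x_i, x_j, m, senders, n)
            m_i = m.scatter_add_rows(senders, n)
        else:
            x_new = x
            m_i = Tensor(np.zeros((n, self.config.hidden_dim)))
        h_new = self.node_update(h, m_i, h0, P, layer)
        return h_new, x_new

    def parameters(self) -> list[Tensor]:
        return (self.phi_e.parameters() + self.phi_x.parameters()
                + self.phi_h.parameters() + [self.W])


class EgnnEncoder:
    def __init__(self, config: EgnnConfig, rng: np.random.Generator):
        self.config = config
        self.proj = glorot(rng, config.input_dim, config.hidden_dim)
        self.layers = [EgclLayer(config, rng) for _ in range(config.n_layers)]

    def forward(self, X: np.ndarray | Tensor, A: np.ndarray, coords: np.ndarray,
                edge_index: np.ndarray, edge_attr: np.ndarray,
                return_coords: bool = False):
        """Run the stacked EGCLs; returns final [L, hidden] embeddings.

        With return_coords=True also returns the per-layer coordinate
        trajectories (used by the equivariance checks).
        """
        X = X if isinstance(X, Tensor) else Tensor(X)
        P = Tensor(normalize_adjacency(A))
        ei, ea = directed_edges(edge_index, edge_attr)
        h0 = X @ self.proj
        h, x = h0, Tensor(np.asarray(coords, dtype=np.float64))
        coord_trace = [x.data.copy()]
        for layer_number, layer in enumerate(self.layers, start=1):
            h, x = layer.forward(h, x, h0, P, ei, ea, layer_number)
            coord_trace.append(x.data.copy())
        if return_coords:
            return h, coord_trace
        return h

    def parameters(self) -> list[Tensor]:
        out = [self.proj]
        for layer in self.layers:
            out.extend(layer.parameters())
        return out
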