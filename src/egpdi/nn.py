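"""Shared neural-network building blocks (parameters, MLPs, schedules)."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["glorot", "Linear", "MLP", "beta_schedule", "normalize_adjacency",
           "residual_identity_update"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform initialized weight matrix."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Tensor]:
        return [self.W] if self.b is None else [self.W, self.b]


class MLP:
    """Two-layer perceptron with SiLU hidden activation.

    `final` selects the output activation: "silu", "linear".
    """

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int,
                 d_out: int, final: str = "linear"):
        self.fc1 = Linear(rng, d_in, d_hidden)
        self.fc2 = Linear(rng, d_hidden, d_out)
        self.final = final

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x).silu()
        out = self.fc2(h)
        if self.final == "silu":
            out = out.silu()
        return out

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.fc2.parameters()


def beta_schedule(lam: float, layer: int) -> float:
    """Identity-mapping strength beta_l = ln(lambda / l + 1) for layer l >= 1.

    Strictly decreasing in l: deeper layers lean ever harder on the identity
    map, which is what lets many layers stack without over-smoothing.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if layer < 1:
        raise ValueError("layer index is 1-based; got l < 1")
    return math.log(lam / layer + 1.0)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalized adjacency P = D̃^(-1/2) (A + I) D̃^(-1/2)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T):
        raise ValueError("A must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def residual_identity_update(h_smooth: Tensor, h0: Tensor, P: Tensor,
                             W: Tensor, alpha: float, beta: float) -> Tensor:
    """sigma(((1-a) P H + a H0) ((1-b) I + b W)) — the shared GCNII-style update."""
    n = W.shape[0]
    mixed = (P @ h_smooth) * (1.0 - alpha) + h0 * alpha
    W_mix = W * beta + Tensor(np.eye(n) * (1.0 - beta))
    return (mixed @ W_mix).relu()
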