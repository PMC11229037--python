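"""Gated multi-head attention fusion of the two branch embeddings.

The GCNII embedding (width 128) and the EGNN embedding (width 512) are
concatenated into f in R^{L x 640}, which serves simultaneously as query,
key and value.  Each of H = 16 heads computes

    Attention_i = softmax( (f W_i^Q)(f W_i^K)^T / sqrt(d_k) ),   d_k = 640/H

and a per-head logistic gate G = sigmoid(f W^G + b^G) modulates the head
output elementwise before the heads are concatenated and mixed by an output
weight.  N = 8 independently parameterized gated blocks run on the same f;
their [L, 640] outputs are stacked into [L, 640, N] and flattened for a
two-layer MLP head ending in a logistic unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Linear, glorot

__all__ = ["FusionConfig", "AttentionHead", "GatedMhaBlock", "GatedFusion",
           "fuse_embeddings"]


@dataclass
class FusionConfig:
    n_heads: int = 16
    n_blocks: int = 8
    d_model: int = 640  # = gcnii hidden (128) + egnn hidden (512)
    mlp_hidden: int = 256
    reduction: str = "flatten"  # "flatten" -> [L, d_model*N]; "mean" over blocks

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")
        if self.reduction not in {"flatten", "mean"}:
            raise ValueError(f"unknown reduction {self.reduction!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def fuse_embeddings(h_gcnii: Tensor | np.ndarray,
                    h_egnn: Tensor | np.ndarray) -> Tensor:
    """Concatenate the branch embeddings (GCNII block first) into f."""
    h_gcnii = h_gcnii if isinstance(h_gcnii, Tensor) else Tensor(h_gcnii)
    h_egnn = h_egnn if isinstance(h_egnn, Tensor) else Tensor(h_egnn)
    if h_gcnii.shape[0] != h_egnn.shape[0]:
        raise ValueError(
            f"branch length mismatch: {h_gcnii.shape[0]} vs {h_egnn.shape[0]}")
    return concat([h_gcnii, h_egnn], axis=1)


class AttentionHead:
    def __init__(self, rng: np.random.Generator, d_model: int, d_k: int):
        self.Wq = glorot(rng, d_model, d_k)
        self.Wk = glorot(rng, d_model, d_k)
        self.Wv = glorot(rng, d_model, d_k)
        self.scale = 1.0 / np.sqrt(d_k)

    def attention(self, f: Tensor) -> Tensor:
        """The [L, L] row-stochastic attention matrix."""
        scores = ((f @ self.Wq) @ (f @ self.Wk).T) * self.scale
        return scores.softmax_rows()

    def __call__(self, f: Tensor) -> Tensor:
        return self.attention(f) @ (f @ self.Wv)

    def parameters(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv]


class GatedMhaBlock:
    """One gated multi-head self-attention block with an output mix."""

    def __init__(self, rng: np.random.Generator, config: FusionConfig):
        d, dk = config.d_model, config.d_k
        self.heads = [AttentionHead(rng, d, dk) for _ in range(config.n_heads)]
        self.gates = [Linear(rng, d, dk) for _ in range(config.n_heads)]
        self.W_out = glorot(rng, d, d)

    def gate(self, f: Tensor, head_index: int) -> Tensor:
        return self.gates[head_index](f).sigmoid()

    def __call__(self, f: Tensor, force_open_gates: bool = False) -> Tensor:
        gated = []
        for k, head in enumerate(self.heads):
            out = head(f)
            if not force_open_gates:
                out = self.gate(f, k) * out
            gated.append(out)
        return concat(gated, axis=1) @ self.W_out

    def parameters(self) -> list[Tensor]:
        out = [self.W_out]
        for h in self.heads:
            out.extend(h.parameters())
        for g in self.gates:
            out.extend(g.parameters())
        return out


class GatedFusion:
    """N independent gated blocks plus the classifying MLP head."""

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        self.config = config
        self.blocks = [GatedMhaBlock(rng, config) for _ in range(config.n_blocks)]
        d_head_in = (config.d_model * config.n_blocks
                     if config.reduction == "flatten" else config.d_model)
        self.head_fc1 = Linear(rng, d_head_in, config.mlp_hidden)
        self.head_fc2 = Linear(rng, config.mlp_hidden, 1)

    def stacked(self, f: Tensor) -> Tensor:
        """Concatenated block outputs, block-major: [L, d_model * N].

        Reshaping to [L, N, d_model] and transposing gives the
        [L, d_model, N] stacked view; slice k of the last axis is block k.
        """
        return concat([blk(f) for blk in self.blocks], axis=1)

    def reduce(self, stacked: Tensor) -> Tensor:
        if self.config.reduction == "flatten":
            return stacked
        L = stacked.shape[0]
        n, d = self.config.n_blocks, self.config.d_model
        return stacked.reshape(L, n, d).sum(axis=1) * (1.0 / n)

    def head_logits(self, fused: Tensor) -> Tensor:
        return self.head_fc2(self.head_fc1(fused).relu())

    def forward_logits(self, h_gcnii, h_egnn) -> Tensor:
        f = fuse_embeddings(h_gcnii, h_egnn)
        return self.head_logits(self.reduce(self.stacked(f)))

    def forward_proba(self, h_gcnii, h_egnn) -> np.ndarray:
        """Per-residue binding probabilities in (0, 1)."""
        return self.forward_logits(h_gcnii, h_egnn).sigmoid().data.ravel()

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for blk in self.blocks:
            out.extend(blk.parameters())
        out.extend(self.head_fc1.parameters())
        out.extend(self.head_fc2.parameters())
        return out
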