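"""The full dual-branch predictor: GCNII + EGNN embeddings fused by gated
multi-head attention, ending in a per-residue binding probability."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .egnn import EgnnConfig, EgnnEncoder
from .features import TOTAL_WIDTH
from .fusion import FusionConfig, GatedFusion, fuse_embeddings
from .gcnii import GcniiConfig, GcniiEncoder
from .structure import ProteinGraph

__all__ = ["ModelConfig", "BindingSitePredictor"]


@dataclass
class ModelConfig:
    egnn: EgnnConfig = field(default_factory=EgnnConfig)
    gcnii: GcniiConfig = field(default_factory=GcniiConfig)
    fusion: FusionConfig | None = None
    input_dim: int = TOTAL_WIDTH

    def __post_init__(self) -> None:
        self.egnn.input_dim = self.input_dim
        self.gcnii.input_dim = self.input_dim
        d_model = self.gcnii.hidden_dim + self.egnn.hidden_dim
        if self.fusion is None:
            n_heads = 16 if d_model % 16 == 0 else 4
            self.fusion = FusionConfig(n_heads=n_heads, d_model=d_model)
        elif self.fusion.d_model != d_model:
            raise ValueError(
                f"fusion d_model {self.fusion.d_model} != gcnii+egnn hidden {d_model}")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale configuration for CPU training on synthetic corpora."""
        return cls(
            egnn=EgnnConfig(n_layers=2, hidden_dim=32, mlp_width=32),
            gcnii=GcniiConfig(n_layers=4, hidden_dim=16),
            fusion=FusionConfig(n_heads=4, n_blocks=2, d_model=48, mlp_hidden=32),
        )


class BindingSitePredictor:
    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.egnn = EgnnEncoder(self.config.egnn, rng)
        self.gcnii = GcniiEncoder(self.config.gcnii, rng)
        self.fusion = GatedFusion(self.config.fusion, rng)

    def forward_logits(self, graph: ProteinGraph) -> Tensor:
        X = Tensor(np.asarray(graph.X, dtype=np.float64))
        h_e = self.egnn.forward(X, graph.A, graph.coords,
                                graph.edge_index, graph.E)
        h_g = self.gcnii.forward(X, graph.A)
        return self.fusion.forward_logits(h_g, h_e)

    def predict_proba(self, graph: ProteinGraph) -> np.ndarray:
        return self.forward_logits(graph).sigmoid().data.ravel()

    def fused_embedding(self, graph: ProteinGraph) -> np.ndarray:
        """The [L, 640] concatenated branch embedding f."""
        X = Tensor(np.asarray(graph.X, dtype=np.float64))
        h_e = self.egnn.forward(X, graph.A, graph.coords,
                                graph.edge_index, graph.E)
        h_g = self.gcnii.forward(X, graph.A)
        return fuse_embeddings(h_g, h_e).data

    def parameters(self) -> list[Tensor]:
        return (self.egnn.parameters() + self.gcnii.parameters()
                + self.fusion.parameters())

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{k}": p.data for k, p in enumerate(self.parameters())}
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path) as f:
            params = self.parameters()
            if len(f.files) != len(params):
                raise ValueError("checkpoint parameter count mismatch")
            for k, p in enumerate(params):
                p.data = np.asarray(f[f"p{k}"], dtype=np.float64)
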