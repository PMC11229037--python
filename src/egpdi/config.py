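"""YAML configuration loading.

Recognized keys (all optional, defaults apply):

    egnn:   {n_layers, hidden_dim, alpha, lambda, mlp_width, dist_scale}
    gcnii:  {n_layers, hidden_dim, alpha, lambda}
    fusion: {n_heads, n_blocks, mlp_hidden, reduction}
    train:  {epochs, learning_rate, weight_decay, input_noise, grad_clip,
             cosine_decay, class_weighting, shuffle}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .egnn import EgnnConfig
from .fusion import FusionConfig
from .gcnii import GcniiConfig
from .model import ModelConfig
from .training import TrainConfig

__all__ = ["load_config"]

_RENAME = {"lambda": "lam"}


def _kwargs(section: dict | None) -> dict:
    return {_RENAME.get(k, k): v for k, v in (section or {}).items()}


def load_config(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    """Read model and training configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    egnn = EgnnConfig(**_kwargs(raw.get("egnn")))
    gcnii = GcniiConfig(**_kwargs(raw.get("gcnii")))
    fusion_kw = _kwargs(raw.get("fusion"))
    fusion = None
    if fusion_kw:
        fusion_kw.setdefault("d_model", gcnii.hidden_dim + egnn.hidden_dim)
        fusion = FusionConfig(**fusion_kw)
    model = ModelConfig(egnn=egnn, gcnii=gcnii, fusion=fusion)
    train = TrainConfig(**_kwargs(raw.get("train")))
    return model, train
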