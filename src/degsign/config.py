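"""Run configuration: one YAML document driving every pipeline stage.

Defaults follow the published protocol: FDR cutoff 0.01, logFC threshold
0, 80:20 splits, five folds, 50 first-level epochs at batch 256, 31
fine-tune epochs at batch 64, Adam at lr 1e-4 / betas (0.9, 0.999) /
eps 1e-8 / weight decay 0, and the seven noise levels
(1, 10, 50, 100, 500, 1000, 1500). One master seed drives splits, folds,
weight initialization, batch shuffling, and noise draws through derived
independent streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .evaluation import BASELINE_IDS, DEFAULT_NOISE_LEVELS
from .model import ModelConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    fdr_cutoff: float = 0.01
    logfc_threshold: float = 0.0
    split_ratio: float = 0.8
    folds: int = 5
    noise_levels: tuple = DEFAULT_NOISE_LEVELS
    baseline_ids: tuple = BASELINE_IDS
    seed: int = 0
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)

    def model_config(self) -> ModelConfig:
        return ModelConfig(**{"seed": self.seed, **self.model})

    def train_config(self) -> TrainConfig:
        return TrainConfig(**{"seed": self.seed, "folds": self.folds, **self.train})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_levels"] = list(self.noise_levels)
        d["baseline_ids"] = list(self.baseline_ids)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)
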