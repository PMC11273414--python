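"""Run configuration: one flat record of every tunable, with defaults.

A YAML config file maps one-to-one onto :class:`RunConfig`; unknown keys
are rejected by name. One global seed fans out to independent derived
streams per pipeline stage (synthesis, splitting, augmentation, weight
initialization, triplet sampling), so fixing the seed fixes the run
while stages stay statistically uncoupled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .objective import LossWeights
from .trainer import TrainConfig

__all__ = ["RunConfig", "derive_seed", "STAGES"]

STAGES = ("synthesis", "split", "augment", "init", "train")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific substream of the global seed, always < 2**31."""
    if stage not in STAGES:
        raise ValueError(f"unknown seed stage {stage!r}; valid: {STAGES}")
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    # data
    image_side: int = 224
    split_ratio: float = 0.8
    split_seed: int = 0
    iqr_factor: float = 1.5
    iqr_per_collection: bool = False
    augment_ops: list = field(default_factory=list)
    # model
    backbone: str = "tiny"
    tap_block: int = -2
    hash_length: int = 32
    n_classes: int = 10
    hidden_dim: int = 64
    classifier_relu: bool = False
    separate_quantizer_bias: bool = False
    # training (reference defaults)
    epochs: int = 50
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    lam: float = 1.0 / 3.0
    beta: float = 1.0
    gamma: float = 1.5
    margin: float = 0.5
    seed: int = 0
    device: str = "cpu"
    # retrieval
    k: int = 10
    truncated_map_normalization: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            loss=LossWeights(lam=self.lam, beta=self.beta, gamma=self.gamma,
                             margin=self.margin),
            seed=derive_seed(self.seed, "train"), hash_length=self.hash_length,
            device=self.device, val_k=self.k,
        )

    def stamp(self) -> dict:
        """Reproducibility stamp written next to run artifacts."""
        from . import __version__

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "seed": self.seed,
            "package_version": __version__,
        }
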