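"""High-level modelling surface: build a model from data, fit it, and
inspect the fitted results.

:class:`DeepHashingModel` bundles the database/query image sets with a
:class:`~dafh.config.RunConfig`; :meth:`DeepHashingModel.fit` runs the
training loop and returns a :class:`HashingResults` carrying the epoch
history, the best validation MAP, the fitted quantizer steepness, and
methods to encode new images, evaluate retrieval, and persist the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, derive_seed
from .data_pipeline import LabeledImage, stratified_split
from .network import DAFHNet, binarize
from .retrieval import EvalReport, RetrievalIndex, evaluate
from .trainer import TrainState, save_checkpoint, train, validate

__all__ = ["DeepHashingModel", "HashingResults"]


class DeepHashingModel:
    """Attention-fusion hashing model bound to a labeled image corpus."""

    def __init__(self, database_images: list[LabeledImage],
                 query_images: list[LabeledImage], config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.database_images = list(database_images)
        self.query_images = list(query_images)
        side = self.database_images[0].pixels.shape[0]
        if side != self.config.image_side:
            self.config.image_side = side
        labels = {im.label for im in self.database_images}
        self.config.n_classes = max(self.config.n_classes, max(labels) + 1)

    @classmethod
    def from_images(cls, images: list[LabeledImage], config: RunConfig | None = None,
                    ) -> "DeepHashingModel":
        """Stratified-split a corpus into database/query sets, then bind."""
        config = config or RunConfig()
        db, q = stratified_split(images, ratio=config.split_ratio,
                                 seed=derive_seed(config.seed, "split"))
        return cls(db, q, config)

    def _build_network(self) -> DAFHNet:
        cfg = self.config
        return DAFHNet(
            hash_length=cfg.hash_length, n_classes=cfg.n_classes,
            image_side=cfg.image_side, hidden_dim=cfg.hidden_dim,
            seed=derive_seed(cfg.seed, "init"),
            classifier_relu=cfg.classifier_relu,
            separate_quantizer_bias=cfg.separate_quantizer_bias,
        )

    def fit(self, log_path: str | Path | None = None,
            checkpoint_dir: str | Path | None = None) -> "HashingResults":
        net = self._build_network()
        net, state = train(self.database_images, self.query_images, net,
                           self.config.train_config(), log_path=log_path,
                           checkpoint_dir=checkpoint_dir)
        return HashingResults(model=self, network=net, state=state)


@dataclass
class HashingResults:
    """A fitted hashing model with its training trajectory."""

    model: DeepHashingModel
    network: DAFHNet
    state: TrainState

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    @property
    def best_map(self) -> float:
        return self.state.best_map

    @property
    def alpha(self) -> float:
        return self.network.alpha_value

    def encode(self, images: list[LabeledImage] | np.ndarray,
               binary: bool = True) -> np.ndarray:
        if isinstance(images, list):
            images = np.stack([im.pixels for im in images])
        codes = self.network.encode(np.asarray(images, dtype=np.float64))
        return binarize(codes) if binary else codes

    def build_index(self) -> RetrievalIndex:
        db = self.model.database_images
        codes = self.encode(db)
        return RetrievalIndex.from_codes(
            codes, [im.label for im in db], [im.source_id for im in db])

    def evaluate(self, k: int | None = None) -> EvalReport:
        k = k if k is not None else self.model.config.k
        index = self.build_index()
        q = self.model.query_images
        codes = self.encode(q)
        return evaluate(index, codes, [im.label for im in q], k=k,
                        query_ids=[im.source_id for im in q],
                        n_classes=self.model.config.n_classes,
                        truncated_normalization=self.model.config.truncated_map_normalization)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = save_checkpoint(self.network, directory / "model")
        self.history.to_csv(directory / "history.csv", index=False)
        return path

    def summary(self) -> str:
        cfg = self.model.config
        hist = self.history
        lines = [
            "Deep Attention Fusion Hashing — fit summary",
            "=" * 46,
            f"hash length L:        {cfg.hash_length}",
            f"classes C:            {cfg.n_classes}",
            f"database / query:     {len(self.model.database_images)} / "
            f"{len(self.model.query_images)}",
            f"epochs run:           {self.state.epoch}",
            f"final train loss:     {hist['train_loss'].iloc[-1]:.4f}"
            if len(hist) else "final train loss:     n/a",
            f"best val MAP@{cfg.k}:      {self.best_map:.4f}",
            f"final val MAP@1:      {hist['val_map1'].iloc[-1]:.4f}"
            if len(hist) else "final val MAP@1:      n/a",
            f"quantizer alpha:      {self.alpha:.4f}",
        ]
        return "\n".join(lines)
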