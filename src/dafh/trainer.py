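"""Training loop for the hashing network.

Each step samples within-batch triplets, runs one forward pass over the
batch, gathers the (anchor, positive, negative) rows, backpropagates
the combined focal + triplet objective and takes an Adam step with L2
weight decay. After every epoch the query set is evaluated against the
database set (MAP@10 and MAP@1) and the best-by-MAP@10 and the last
checkpoints are kept. Given one seed, a run is reproducible bit for bit
on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam
from .data_pipeline import LabeledImage
from .network import DAFHNet, binarize
from .objective import LossWeights, sample_triplets, total_loss
from .retrieval import RetrievalIndex, evaluate

__all__ = ["TrainConfig", "TrainState", "train", "validate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the reference settings."""

    epochs: int = 50
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    loss: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    hash_length: int = 32
    device: str = "cpu"
    val_k: int = 10

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError(f"unknown device {self.device!r}")


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    best_map: float = -1.0
    history: list[dict] = field(default_factory=list)


def _stack(images: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pixels = np.stack([im.pixels for im in images]).astype(np.float64)
    labels = np.array([im.label for im in images], dtype=np.int64)
    ids = [im.source_id for im in images]
    return pixels, labels, ids


def validate(model: DAFHNet, query_images: list[LabeledImage],
             database_images: list[LabeledImage], k: int = 10) -> dict:
    """Encode both sets, index the database side, evaluate the queries."""
    if not query_images or not database_images:
        raise ValueError("validation needs non-empty query and database sets")
    db_px, db_labels, db_ids = _stack(database_images)
    q_px, q_labels, q_ids = _stack(query_images)
    db_codes = binarize(model.encode(db_px))
    q_codes = binarize(model.encode(q_px))
    index = RetrievalIndex.from_codes(db_codes, db_labels, db_ids)
    report = evaluate(index, q_codes, q_labels, k=k, query_ids=q_ids)
    return {"map_at_k": report.map_at_k, "map_at_1": report.map_at_1, "k": k}


def train(database_images: list[LabeledImage], query_images: list[LabeledImage],
          model: DAFHNet, cfg: TrainConfig, log_path: str | Path | None = None,
          checkpoint_dir: str | Path | None = None) -> tuple[DAFHNet, TrainState]:
    """Run the full training loop; returns the trained model and its state."""
    labels_all = {im.label for im in database_images}
    if len(labels_all) < 2:
        raise ValueError("training needs at least 2 classes in the database set")
    pixels, labels, _ = _stack(database_images)
    n = len(database_images)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate,
                     weight_decay=cfg.weight_decay)
    state = TrainState()
    log_file = open(log_path, "a") if log_path is not None else None
    try:
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                batch_idx = perm[start:start + cfg.batch_size]
                batch_labels = labels[batch_idx]
                triplet_seed = int(rng.integers(0, 2 ** 31))
                triplets = sample_triplets(batch_labels, rng_seed=triplet_seed)
                if len(triplets) == 0:
                    continue
                out = model(pixels[batch_idx])
                out_a = out.select(triplets.anchor_idx)
                out_p = out.select(triplets.positive_idx)
                out_n = out.select(triplets.negative_idx)
                lbl = (batch_labels[triplets.anchor_idx],
                       batch_labels[triplets.positive_idx],
                       batch_labels[triplets.negative_idx])
                loss, breakdown = total_loss(out_a, out_p, out_n, lbl, cfg.loss)
                if not np.isfinite(breakdown["total"]):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch} "
                        f"step {state.step} ({breakdown})")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                state.step += 1
                epoch_losses.append(breakdown["total"])
                if log_file is not None:
                    record = {"epoch": epoch, "step": state.step,
                              "alpha": model.alpha_value, **breakdown}
                    log_file.write(json.dumps(record) + "\n")
            assert model.alpha_value > 1.0, "quantizer steepness left its domain"
            metrics = validate(model, query_images, database_images, k=cfg.val_k)
            state.epoch = epoch + 1
            entry = {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
                "val_map10": metrics["map_at_k"],
                "val_map1": metrics["map_at_1"],
                "alpha": model.alpha_value,
            }
            state.history.append(entry)
            if checkpoint_dir is not None:
                save_checkpoint(model, Path(checkpoint_dir) / "last")
            if metrics["map_at_k"] > state.best_map:
                state.best_map = metrics["map_at_k"]
                if checkpoint_dir is not None:
                    save_checkpoint(model, Path(checkpoint_dir) / "best")
    finally:
        if log_file is not None:
            log_file.close()
    return model, state


def save_checkpoint(model: DAFHNet, path: str | Path) -> Path:
    """Parameter archive (.npz) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(model.config_dict(), indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> DAFHNet:
    path = Path(path)
    config = json.loads(path.with_suffix(".json").read_text())
    model = DAFHNet(
        hash_length=config["hash_length"], n_classes=config["n_classes"],
        image_side=config["image_side"], in_channels=config["in_channels"],
        classifier_relu=config["classifier_relu"],
        separate_quantizer_bias=config["separate_quantizer_bias"],
    )
    with np.load(path.with_suffix(".npz")) as arrs:
        model.load_state_dict(dict(arrs))
    return model
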