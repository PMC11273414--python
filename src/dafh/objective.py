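"""Multi-task training objective: focal classification loss on each
triplet member plus a margin-based triplet loss on the continuous codes.

total = lam * (focal(anchor) + focal(positive) + focal(negative))
        + beta * triplet(anchor, positive, negative)

with lam = 1/3 (making the classification part an average over the
three members) and beta = 1 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .network import HashOutput

__all__ = [
    "LossWeights",
    "TripletBatch",
    "focal_loss",
    "triplet_loss",
    "total_loss",
    "sample_triplets",
    "EPS_LOG",
]

EPS_LOG = 1e-12  # floor inside log


@dataclass
class LossWeights:
    lam: float = 1.0 / 3.0    # weight on summed focal terms
    beta: float = 1.0         # weight on the triplet term
    gamma: float = 1.5        # focal focusing exponent
    margin: float = 0.5       # triplet margin

    def __post_init__(self):
        for name in ("lam", "beta", "gamma", "margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TripletBatch:
    """Parallel (anchor, positive, negative) index triples into a batch."""

    anchor_idx: np.ndarray
    positive_idx: np.ndarray
    negative_idx: np.ndarray
    n_skipped: int = 0

    def __len__(self):
        return len(self.anchor_idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def focal_loss(probs, y, gamma: float = 1.5) -> Tensor:
    """Mean focal loss -(1 - p_y)^gamma * log(p_y) over a batch.

    ``probs`` is (N, C) rows on the simplex (a single vector is promoted
    to a batch of one); ``y`` the integer true classes.
    """
    probs = _as_tensor(probs)
    if probs.ndim == 1:
        probs = probs.reshape(1, -1)
    y = np.atleast_1d(np.asarray(y, dtype=np.intp))
    n, c = probs.shape
    if np.any((y < 0) | (y >= c)):
        raise ValueError(f"labels out of range [0, {c}): {y}")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), y] = 1.0
    p_y = (probs * onehot).sum(axis=1).clamp(EPS_LOG, 1.0)
    loss = -((1.0 - p_y) ** float(gamma)) * p_y.log()
    return loss.mean()


def _euclidean(a: Tensor, b: Tensor) -> Tensor:
    # small floor keeps the sqrt differentiable when the codes coincide
    return (((a - b) ** 2).sum(axis=1) + EPS_LOG).sqrt()


def triplet_loss(a, p, n, margin: float = 0.5, squared: bool = False) -> Tensor:
    """Mean of max(0, d(a,p) - d(a,n) + margin) with Euclidean d."""
    a, p, n = _as_tensor(a), _as_tensor(p), _as_tensor(n)
    if a.ndim == 1:
        a, p, n = a.reshape(1, -1), p.reshape(1, -1), n.reshape(1, -1)
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"triplet shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    if squared:
        d_ap = ((a - p) ** 2).sum(axis=1)
        d_an = ((a - n) ** 2).sum(axis=1)
    else:
        d_ap, d_an = _euclidean(a, p), _euclidean(a, n)
    return (d_ap - d_an + margin).relu().mean()


def total_loss(outputs_a: HashOutput, outputs_p: HashOutput, outputs_n: HashOutput,
               labels: tuple, w: LossWeights) -> tuple[Tensor, dict]:
    """Combined objective and a per-term breakdown for logging.

    ``labels`` is the triple (anchor, positive, negative) of integer
    label arrays aligned with the three outputs.
    """
    ya, yp, yn = (np.atleast_1d(np.asarray(v, dtype=np.intp)) for v in labels)
    f_a = focal_loss(outputs_a.probs, ya, w.gamma)
    f_p = focal_loss(outputs_p.probs, yp, w.gamma)
    f_n = focal_loss(outputs_n.probs, yn, w.gamma)
    trip = triplet_loss(outputs_a.code_cont, outputs_p.code_cont,
                        outputs_n.code_cont, w.margin)
    total = w.lam * (f_a + f_p + f_n) + w.beta * trip
    breakdown = {
        "focal_a": f_a.item(), "focal_p": f_p.item(), "focal_n": f_n.item(),
        "triplet": trip.item(), "total": total.item(),
    }
    return total, breakdown


def sample_triplets(labels, rng_seed: int = 0, codes: np.ndarray | None = None,
                    semi_hard: bool = False, margin: float = 0.5) -> TripletBatch:
    """Within-batch triplet sampling, uniform by default.

    Every element with at least one same-class partner and at least one
    different-class element serves as anchor exactly once; its positive
    is drawn uniformly from same-class others, its negative uniformly
    from the other classes. Anchors without a valid partner are skipped
    and counted in ``n_skipped``.

    With ``semi_hard=True`` (requires the batch ``codes``), the negative
    is instead the closest one satisfying d(a,p) < d(a,n) < d(a,p)+margin
    when such exists, else the hardest (closest) negative.
    """
    labels = np.asarray(labels)
    if semi_hard and codes is None:
        raise ValueError("semi-hard mining needs the batch codes")
    rng = np.random.default_rng(rng_seed)
    anchors, positives, negatives = [], [], []
    skipped = 0
    for i, y in enumerate(labels):
        same = np.flatnonzero(labels == y)
        same = same[same != i]
        other = np.flatnonzero(labels != y)
        if len(same) == 0 or len(other) == 0:
            skipped += 1
            continue
        anchors.append(i)
        pos = int(rng.choice(same))
        positives.append(pos)
        if semi_hard:
            d = np.linalg.norm(codes[other] - codes[i], axis=1)
            d_ap = float(np.linalg.norm(codes[pos] - codes[i]))
            band = other[(d > d_ap) & (d < d_ap + margin)]
            if len(band):
                db = np.linalg.norm(codes[band] - codes[i], axis=1)
                negatives.append(int(band[np.argmin(db)]))
            else:
                negatives.append(int(other[np.argmin(d)]))
        else:
            negatives.append(int(rng.choice(other)))
    if not anchors and len(labels) > 0:
        warnings.warn("no valid triplets in batch (single class or all singletons)",
                      stacklevel=2)
    return TripletBatch(
        anchor_idx=np.asarray(anchors, dtype=np.intp),
        positive_idx=np.asarray(positives, dtype=np.intp),
        negative_idx=np.asarray(negatives, dtype=np.intp),
        n_skipped=skipped,
    )
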