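"""Binary-code retrieval and ranking-quality evaluation.

Codes in {-1,+1}^L are bit-packed into 64-bit words; Hamming distances
are computed with XOR + popcount and queries answered by an exact linear
scan. Ranking ties at equal distance break by ascending database index,
so results are deterministic across platforms.

Evaluation follows the standard retrieval protocol: average precision
per query, its mean over queries (MAP), the depth-limited MAP@k, and a
class confusion matrix of the rank-1 result (whose class-weighted
diagonal equals MAP@1, i.e. top-1 retrieval accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "pack_codes",
    "unpack_codes",
    "hamming",
    "RetrievalIndex",
    "RankedResult",
    "EvalReport",
    "average_precision",
    "mean_average_precision",
    "map1_confusion",
    "evaluate",
    "write_code_table",
    "read_code_table",
]


def _to_bits(codes: np.ndarray) -> np.ndarray:
    """Map {-1,+1} (or {0,1}) codes to {0,1} uint8 bits."""
    arr = np.asarray(codes)
    if arr.ndim == 1:
        arr = arr[None, :]
    bits = np.where(arr > 0, 1, 0).astype(np.uint8)
    return bits


def pack_codes(codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Pack sign codes into uint64 words; returns (packed (N, W), L)."""
    bits = _to_bits(codes)
    n, length = bits.shape
    n_words = (length + 63) // 64
    padded = np.zeros((n, n_words * 64), dtype=np.uint8)
    padded[:, :length] = bits
    weights = (np.uint64(1) << np.arange(64, dtype=np.uint64))
    packed = (padded.reshape(n, n_words, 64).astype(np.uint64) * weights).sum(axis=2)
    return packed.astype(np.uint64), length

def unpack_codes(packed: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`, back to {-1,+1} codes."""
    packed = np.asarray(packed, dtype=np.uint64)
    n, n_words = packed.shape
    shifts = np.arange(64, dtype=np.uint64)
    bits = ((packed[:, :, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    bits = bits.reshape(n, n_words * 64)[:, :length]
    return np.where(bits > 0, 1.0, -1.0)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two codes of equal length L (popcount)."""
    a, b = np.atleast_1d(np.asarray(a)), np.atleast_1d(np.asarray(b))
    if a.shape != b.shape:
        raise ValueError(f"code length mismatch: {a.shape} vs {b.shape}")
    pa, la = pack_codes(a)
    pb, _ = pack_codes(b)
    return int(np.bitwise_count(pa ^ pb).sum())


@dataclass
class RankedResult:
    """Database permutation by ascending distance, index-tie-broken."""

    order: np.ndarray      # database indices, best first
    distances: np.ndarray  # aligned integer Hamming distances


@dataclass
class RetrievalIndex:
    """Bit-packed code database with aligned labels and source ids."""

    packed: np.ndarray          # (N, W) uint64
    length: int                 # L, bits per code
    labels: np.ndarray          # (N,) int
    ids: list[str] = field(default_factory=list)

    @classmethod
    def from_codes(cls, codes: np.ndarray, labels, ids=None) -> "RetrievalIndex":
        packed, length = pack_codes(codes)
        labels = np.asarray(labels, dtype=np.int64)
        if packed.shape[0] != labels.shape[0]:
            raise ValueError("codes and labels must align")
        ids = list(ids) if ids is not None else [str(i) for i in range(len(labels))]
        return cls(packed=packed, length=length, labels=labels, ids=ids)

    def __len__(self):
        return self.packed.shape[0]

    def distances_to(self, code: np.ndarray) -> np.ndarray:
        pq, lq = pack_codes(code)
        if lq != self.length:
            raise ValueError(f"query code has {lq} bits, index has {self.length}")
        return np.bitwise_count(self.packed ^ pq).sum(axis=1).astype(np.int64)

    def query(self, code: np.ndarray, k: int | None = None,
              exclude_id: str | None = None) -> RankedResult:
        """Top-k exact Hamming search; ``k`` is clamped to the index size.

        ``exclude_id`` drops the database entry with that source id from
        the candidate list (self-match exclusion for overlapping sets).
        """
        if len(self) == 0:
            raise ValueError("cannot query an empty index")
        dist = self.distances_to(code)
        candidates = np.arange(len(self))
        if exclude_id is not None and self.ids:
            keep = np.array([i != exclude_id for i in self.ids])
            candidates, dist = candidates[keep], dist[keep]
        order = candidates[np.argsort(dist, kind="stable")]
        dist_sorted = np.sort(dist, kind="stable")
        if k is not None:
            k = min(k, len(order))
            order, dist_sorted = order[:k], dist_sorted[:k]
        return RankedResult(order=order, distances=dist_sorted)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), packed=self.packed, labels=self.labels)
        header = {"L": self.length, "N": len(self), "ids": self.ids}
        path.with_suffix(".json").write_text(json.dumps(header))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "RetrievalIndex":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        header = json.loads(path.with_suffix(".json").read_text())
        return cls(packed=arrs["packed"].astype(np.uint64), length=int(header["L"]),
                   labels=arrs["labels"], ids=list(header["ids"]))


# -- ranking metrics ---------------------------------------------------------

def average_precision(relevance, n_gt: int) -> float:
    """AP = (1/n_gt) * sum_k P(k) * r(k) over the returned ranking.

    ``relevance`` is the binary relevance of each returned result in rank
    order; ``n_gt`` the number of relevant items the normalization assumes.
    """
    if n_gt < 1:
        raise ValueError("average precision undefined with no relevant items (n_gt=0)")
    rel = np.asarray(relevance, dtype=np.float64)
    if rel.sum() > n_gt:
        raise ValueError(f"ranking contains {int(rel.sum())} relevant items but n_gt={n_gt}")
    if rel.size == 0:
        return 0.0
    cum = np.cumsum(rel)
    precision_at_k = cum / np.arange(1, rel.size + 1)
    return float((precision_at_k * rel).sum() / n_gt)


def mean_average_precision(relevance_lists, n_gts, k: int | None = None,
                           truncated_normalization: bool = True) -> float:
    """MAP = mean over queries of AP, optionally truncated to the top k.

    With ``truncated_normalization`` (the default) the AP of a top-k list
    is normalized by min(n_gt, k), so a perfect truncated list scores 1
    and MAP@1 equals top-1 accuracy; the flag off keeps the full-corpus
    n_gt in the denominator.
    """
    relevance_lists = list(relevance_lists)
    n_gts = list(n_gts)
    if len(relevance_lists) == 0:
        raise ValueError("MAP over an empty query set is undefined")
    if len(relevance_lists) != len(n_gts):
        raise ValueError("relevance lists and n_gt counts must align")
    aps = []
    for rel, n_gt in zip(relevance_lists, n_gts):
        rel = np.asarray(rel)
        if k is not None:
            rel = rel[:k]
            denom = min(int(n_gt), k) if truncated_normalization else int(n_gt)
        else:
            denom = int(n_gt)
        aps.append(average_precision(rel, denom))
    return float(np.mean(aps))


def map1_confusion(query_labels, retrieved_top1_labels, n_classes: int) -> np.ndarray:
    """Row-normalized C x C matrix of (query class -> rank-1 result class)."""
    q = np.asarray(query_labels, dtype=np.intp)
    r = np.asarray(retrieved_top1_labels, dtype=np.intp)
    mat = np.zeros((n_classes, n_classes))
    np.add.at(mat, (q, r), 1.0)
    row_sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(row_sums > 0, mat / row_sums, 0.0)
    return mat


@dataclass
class EvalReport:
    """Full retrieval evaluation for one query set against one index."""

    ap_per_query: np.ndarray
    map: float
    map_at_k: float
    map_at_1: float
    k: int
    confusion_map1: np.ndarray

    def to_dict(self) -> dict:
        return {
            "map": self.map,
            "map_at_k": self.map_at_k,
            "map_at_1": self.map_at_1,
            "k": self.k,
            "ap_per_query": self.ap_per_query.tolist(),
            "confusion_map1": self.confusion_map1.tolist(),
        }


def evaluate(index: RetrievalIndex, query_codes: np.ndarray, query_labels,
             k: int = 10, query_ids=None, n_classes: int | None = None,
             truncated_normalization: bool = True) -> EvalReport:
    """Rank every query against the index and aggregate the metrics.

    Relevance = same class label. When a query's source id matches a
    database id (overlapping sets), that entry is excluded from its
    candidate list.
    """
    query_labels = np.asarray(query_labels, dtype=np.int64)
    if len(index) == 0 or query_labels.size == 0:
        raise ValueError("evaluation needs a non-empty index and query set")
    if n_classes is None:
        n_classes = int(max(index.labels.max(), query_labels.max())) + 1
    db_ids = set(index.ids)
    aps, rels, n_gts, top1 = [], [], [], []
    codes = np.atleast_2d(np.asarray(query_codes))
    for qi in range(codes.shape[0]):
        qid = None
        if query_ids is not None and query_ids[qi] in db_ids:
            qid = query_ids[qi]
        ranked = index.query(codes[qi], k=None, exclude_id=qid)
        rel = (index.labels[ranked.order] == query_labels[qi]).astype(np.float64)
        n_gt = int(rel.sum())
        if n_gt == 0:
            # no same-class item in the database: this query contributes AP 0
            aps.append(0.0)
            rels.append(rel)
            n_gts.append(1)
            top1.append(int(index.labels[ranked.order[0]]))
            continue
        aps.append(average_precision(rel, n_gt))
        rels.append(rel)
        n_gts.append(n_gt)
        top1.append(int(index.labels[ranked.order[0]]))
    map_full = float(np.mean(aps))
    map_k = mean_average_precision(rels, n_gts, k=k,
                                   truncated_normalization=truncated_normalization)
    map_1 = mean_average_precision(rels, n_gts, k=1,
                                   truncated_normalization=truncated_normalization)
    conf = map1_confusion(query_labels, top1, n_classes)
    return EvalReport(ap_per_query=np.asarray(aps), map=map_full, map_at_k=map_k,
                      map_at_1=map_1, k=k, confusion_map1=conf)


# -- code-table I/O ----------------------------------------------------------

def write_code_table(codes: np.ndarray, labels, ids, path: str | Path) -> Path:
    """CSV with columns source_id,label,bit_0..bit_{L-1}; bits in {0,1}."""
    bits = _to_bits(codes)
    n, length = bits.shape
    df = pd.DataFrame({"source_id": list(ids), "label": np.asarray(labels)})
    for j in range(length):
        df[f"bit_{j}"] = bits[:, j]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_code_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a code table back to ({-1,+1} codes, labels, ids)."""
    df = pd.read_csv(path)
    bit_cols = sorted((c for c in df.columns if c.startswith("bit_")),
                      key=lambda c: int(c.split("_")[1]))
    bits = df[bit_cols].to_numpy()
    codes = np.where(bits > 0, 1.0, -1.0)
    return codes, df["label"].to_numpy(), df["source_id"].astype(str).tolist()
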