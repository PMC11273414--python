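"""Image ingestion, standardization, cleaning, augmentation and splitting.

The pipeline mirrors a conventional radiology-retrieval preparation
workflow: DICOM slices are converted to min-max normalized, square
grayscale arrays; corpus-level outliers are fenced out by the
interquartile-range rule on per-image mean and variance; stochastic
augmentations simulate acquisition variability; and a stratified split
produces the retrieval database (also the training corpus) and the
held-out query set.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "Split",
    "LabeledImage",
    "ImageStats",
    "convert_dicom",
    "load_png",
    "write_png",
    "iqr_clean",
    "augment",
    "stratified_split",
    "read_manifest",
    "write_manifest",
    "corpus_stats",
    "write_stats_json",
    "AUGMENT_RANGES",
    "DEFAULT_SIDE",
]

DEFAULT_SIDE = 224

# default parameter ranges for stochastic augmentation (sampled uniformly)
AUGMENT_RANGES: dict[str, tuple[float, float]] = {
    "noise": (0.0, 0.05),        # additive Gaussian sd, intensity units
    "blur": (0.0, 1.5),          # Gaussian blur sd, pixels
    "brightness": (-0.2, 0.2),   # additive delta
    "rotation": (-15.0, 15.0),   # degrees
    "scaling": (0.9, 1.1),       # isotropic zoom factor about the center
}


class Split(enum.Enum):
    UNASSIGNED = "unassigned"
    DATABASE = "database"
    QUERY = "query"


@dataclass
class LabeledImage:
    """One standardized grayscale image with its class label.

    ``pixels`` is a 2-D float array with values in [0, 1]. ``label`` indexes
    the class vocabulary; -1 marks an image whose label is not yet known.
    """

    pixels: np.ndarray
    label: int = -1
    source_id: str = ""
    split: Split = Split.UNASSIGNED

    @property
    def mean(self) -> float:
        return float(self.pixels.mean())

    @property
    def variance(self) -> float:
        return float(self.pixels.var())


@dataclass
class ImageStats:
    """Corpus-level summary of a per-image statistic distribution."""

    mean: np.ndarray       # per-image means
    variance: np.ndarray   # per-image variances
    q1: dict[str, float]
    q3: dict[str, float]

    @property
    def iqr(self) -> dict[str, float]:
        return {k: self.q3[k] - self.q1[k] for k in self.q1}


def _minmax(arr: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant image maps to all zeros."""
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def standardize(arr: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Min-max scale then resample to ``side`` x ``side``."""
    arr = _minmax(arr)
    if arr.shape != (side, side):
        arr = _sk_resize(arr, (side, side), order=1, anti_aliasing=True,
                         preserve_range=True)
    return np.clip(arr, 0.0, 1.0)


def convert_dicom(dicom_path: str | Path, side: int = DEFAULT_SIDE,
                  label: int = -1) -> LabeledImage:
    """Read a single-slice DICOM file into a standardized :class:`LabeledImage`.

    Raises ``ValueError`` naming the file when the pixel data is missing or
    unreadable.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    path = Path(dicom_path)
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except (InvalidDicomError, FileNotFoundError, OSError, AttributeError) as exc:
        raise ValueError(f"cannot read DICOM pixel data from {path}: {exc}") from exc
    if arr.ndim == 3:  # multi-frame or RGB: collapse to one gray slice
        arr = arr.mean(axis=-1) if arr.shape[-1] in (3, 4) else arr[0]
    return LabeledImage(pixels=standardize(arr, side), label=label,
                        source_id=str(path))


def load_png(path: str | Path, side: int | None = None, label: int = -1) -> LabeledImage:
    arr = np.asarray(PILImage.open(path).convert("L"), dtype=np.float64) / 255.0
    if side is not None and arr.shape != (side, side):
        arr = standardize(arr, side)
    return LabeledImage(pixels=arr, label=label, source_id=str(path))


def write_png(image: LabeledImage, path: str | Path) -> Path:
    """Serialize at 8-bit depth; reading back reproduces the quantized values."""
    path = Path(path)
    u8 = np.round(np.clip(image.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    PILImage.fromarray(u8, mode="L").save(path)
    return path


def corpus_stats(images: list[LabeledImage]) -> ImageStats:
    means = np.array([im.mean for im in images])
    varis = np.array([im.variance for im in images])
    q1 = {"mean": float(np.percentile(means, 25)),
          "variance": float(np.percentile(varis, 25))}
    q3 = {"mean": float(np.percentile(means, 75)),
          "variance": float(np.percentile(varis, 75))}
    return ImageStats(mean=means, variance=varis, q1=q1, q3=q3)


def iqr_clean(images: list[LabeledImage], factor: float = 1.5,
              ) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Fence outliers on per-image mean and variance.

    An image is removed iff its mean or its variance falls outside
    ``[Q1 - factor*IQR, Q3 + factor*IQR]`` of the corpus distribution of
    that statistic. Returns ``(kept, removed)``, each preserving the input
    order; together they partition the input exactly.
    """
    if len(images) < 4:
        raise ValueError(
            f"IQR cleaning needs at least 4 images to define quartiles, got {len(images)}")
    stats = corpus_stats(images)
    kept: list[LabeledImage] = []
    removed: list[LabeledImage] = []
    if not np.isfinite(factor):  # unbounded fence keeps everything
        return list(images), []
    lo = {k: stats.q1[k] - factor * stats.iqr[k] for k in stats.q1}
    hi = {k: stats.q3[k] + factor * stats.iqr[k] for k in stats.q3}
    for im, m, v in zip(images, stats.mean, stats.variance):
        ok = (lo["mean"] <= m <= hi["mean"]) and (lo["variance"] <= v <= hi["variance"])
        (kept if ok else removed).append(im)
    return kept, removed


def _apply_scaling(arr: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return arr
    h, w = arr.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(arr, matrix, offset=offset, order=1,
                                    mode="nearest")


def augment(image: LabeledImage, ops: set | dict, rng_seed: int = 0) -> LabeledImage:
    """Apply a subset of {noise, blur, brightness, rotation, scaling}.

    ``ops`` is either a set of operation names (parameters drawn uniformly
    from :data:`AUGMENT_RANGES` using ``rng_seed``) or a mapping from name
    to an explicit parameter. The same seed and ops always produce the
    same output; values are clipped to [0, 1].
    """
    names = set(ops)
    unknown = names - set(AUGMENT_RANGES)
    if unknown:
        raise ValueError(
            f"unknown augmentation op(s) {sorted(unknown)}; valid ops are "
            f"{sorted(AUGMENT_RANGES)}")
    rng = np.random.default_rng(rng_seed)
    params: dict[str, float] = {}
    # draw in a fixed name order so determinism is independent of set order
    for name in sorted(names):
        if isinstance(ops, dict) and ops[name] is not None:
            params[name] = float(ops[name])
        else:
            lo, hi = AUGMENT_RANGES[name]
            params[name] = float(rng.uniform(lo, hi))

    arr = image.pixels.astype(np.float64)
    if "rotation" in params and params["rotation"] != 0.0:
        arr = ndimage.rotate(arr, params["rotation"], reshape=False, order=1,
                             mode="nearest")
    if "scaling" in params:
        arr = _apply_scaling(arr, params["scaling"])
    if "blur" in params and params["blur"] > 0.0:
        arr = ndimage.gaussian_filter(arr, sigma=params["blur"])
    if "brightness" in params:
        arr = arr + params["brightness"]
    if "noise" in params and params["noise"] > 0.0:
        arr = arr + rng.normal(0.0, params["noise"], size=arr.shape)
    arr = np.clip(arr, 0.0, 1.0)
    return LabeledImage(pixels=arr, label=image.label,
                        source_id=image.source_id, split=image.split)


def stratified_split(images: list[LabeledImage], ratio: float = 0.8,
                     seed: int = 0) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Per-class split into (database, query) with |database_c| = round(ratio*n_c).

    Rounding is half-to-even; the shortfall goes to the query side. The
    database side doubles as the training corpus and retrieval database.
    """
    by_class: dict[int, list[int]] = {}
    for i, im in enumerate(images):
        by_class.setdefault(im.label, []).append(i)
    for label, idxs in sorted(by_class.items()):
        if len(idxs) < 2:
            raise ValueError(f"class {label} has {len(idxs)} image(s); need >= 2 to split")
    rng = np.random.default_rng(seed)
    database: list[LabeledImage] = []
    query: list[LabeledImage] = []
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        n_db = int(np.round(ratio * len(idxs)))  # numpy rounds half to even
        for j, i in enumerate(idxs):
            im = images[i]
            im.split = Split.DATABASE if j < n_db else Split.QUERY
            (database if j < n_db else query).append(im)
    return database, query


# -- manifest / stats I/O ----------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing column(s) {sorted(missing)}")
    if "collection" not in df.columns:
        df["collection"] = ""
    return df


def load_from_manifest(manifest: pd.DataFrame, side: int = DEFAULT_SIDE,
                       root: str | Path = ".") -> list[LabeledImage]:
    images = []
    for _, row in manifest.iterrows():
        p = Path(root) / str(row["path"])
        if p.suffix.lower() in (".dcm", ".dicom"):
            im = convert_dicom(p, side=side, label=int(row["label"]))
        else:
            im = load_png(p, side=side, label=int(row["label"]))
        images.append(im)
    return images


def write_manifest(images: list[LabeledImage], path: str | Path,
                   kept_flags: list[bool] | None = None) -> Path:
    rows = []
    for i, im in enumerate(images):
        rows.append({
            "path": im.source_id,
            "label": im.label,
            "kept": True if kept_flags is None else bool(kept_flags[i]),
            "split": im.split.value,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_stats_json(images: list[LabeledImage], path: str | Path) -> Path:
    stats = corpus_stats(images)
    payload = {
        "per_image": [
            {"source_id": im.source_id, "mean": im.mean, "variance": im.variance}
            for im in images
        ],
        "quartiles": {"q1": stats.q1, "q3": stats.q3, "iqr": stats.iqr},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
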