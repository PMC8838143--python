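"""Duplicate-image elimination by grayscale intensity correlation.

Curated dermoscopy archives accumulate re-submitted images of the same
lesion under different names.  To remove them, each image is converted
to grayscale (luma weights 0.299/0.587/0.114) and pairs are scored with
the Pearson-type normalized cross-correlation of their pixel grids
(each grid centered by its scalar mean intensity).  A pair correlating
above 0.99 is considered identical and the later copy is discarded.

The 256-bin intensity histograms of each pair are retained for
reporting, and a ``histogram`` mode correlating the histograms instead
of the pixel grids is available; pixel (``image``) mode is canonical,
since the spatial double sum of the correlation is only defined on
aligned grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import ImageRecord
from .preprocess import resize_bilinear

__all__ = [
    "LUMA_WEIGHTS",
    "GrayPair",
    "DedupReport",
    "to_grayscale",
    "image_correlation",
    "deduplicate",
]

#: ITU-R BT.601 luma weights (R, G, B)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: common grid both images are resized to when their shapes differ
CORRELATION_SIZE = 128


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse H x W x 3 to a real-valued H x W luma grid."""
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected HxWx3 array, got shape {px.shape}")
    r, g, b = LUMA_WEIGHTS
    return r * px[..., 0].astype(np.float64) + g * px[..., 1] + b * px[..., 2]


@dataclass
class GrayPair:
    """A pair of aligned grayscale grids with their histograms and means."""

    a: np.ndarray
    b: np.ndarray
    hist_a: np.ndarray = field(init=False)
    hist_b: np.ndarray = field(init=False)
    mean_a: float = field(init=False)
    mean_b: float = field(init=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.a.shape != self.b.shape:
            raise ValueError(
                f"grids must be aligned, got {self.a.shape} vs {self.b.shape}"
            )
        self.hist_a = np.histogram(self.a, bins=256, range=(0, 256))[0]
        self.hist_b = np.histogram(self.b, bins=256, range=(0, 256))[0]
        self.mean_a = float(self.a.mean())
        self.mean_b = float(self.b.mean())


def image_correlation(pair: GrayPair, *, mode: str = "image") -> float:
    """Normalized cross-correlation of a pair, in [-1, 1].

    ``image`` mode correlates the mean-centered pixel grids (canonical);
    ``histogram`` mode correlates the mean-centered 256-bin histograms.
    A constant input has no variance; its correlation is defined as 0
    (with a warning) rather than NaN.
    """
    if mode == "image":
        x, y = pair.a - pair.mean_a, pair.b - pair.mean_b
    elif mode == "histogram":
        ha = pair.hist_a.astype(np.float64)
        hb = pair.hist_b.astype(np.float64)
        x, y = ha - ha.mean(), hb - hb.mean()
    else:
        raise ValueError(f"mode must be 'image' or 'histogram', got {mode!r}")
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0.0:
        warnings.warn(
            "correlation of a constant image is undefined; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float((x * y).sum() / denom)


@dataclass
class DedupReport:
    kept: list[str]
    removed: list[tuple[str, str, float]]  # (removed_id, kept_id, correlation)


def _aligned_gray(record: ImageRecord, size: int) -> np.ndarray:
    gray = to_grayscale(record.pixels)
    if gray.shape != (size, size):
        gray = resize_bilinear(gray, size)
    return gray


def deduplicate(
    records: list[ImageRecord],
    threshold: float = 0.99,
    *,
    mode: str = "image",
) -> DedupReport:
    """Greedy duplicate scan in manifest order.

    Each record is compared against all previously kept records; it is
    discarded if any correlation strictly exceeds ``threshold`` (the
    first occurrence is always kept).  Differently sized images are
    resized to a common 128 x 128 grid before correlation.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[str] = []
    kept_gray: list[np.ndarray] = []
    removed: list[tuple[str, str, float]] = []
    for rec in records:
        gray = _aligned_gray(rec, CORRELATION_SIZE)
        match = None
        for kid, kgray in zip(kept, kept_gray):
            corr = image_correlation(GrayPair(gray, kgray), mode=mode)
            if corr > threshold:
                match = (rec.id, kid, corr)
                break
        if match is not None:
            removed.append(match)
        else:
            kept.append(rec.id)
            kept_gray.append(gray)
    return DedupReport(kept=kept, removed=removed)
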