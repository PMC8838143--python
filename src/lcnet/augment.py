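"""Class balancing and online training-time augmentation.

Dermoscopy datasets are skewed (benign lesions outnumber melanomas or
vice versa), which biases a classifier toward the majority class.  Two
remedies are combined, both restricted to the training split:

* random oversampling — minority-class ids are drawn uniformly with
  replacement until every class matches the largest class;
* online augmentation — each training image is perturbed per batch by
  a random rotation (+-30 degrees), an anisotropic scale jitter (X in
  [0.8, 1], Y fixed at 1) and an integer translation (+-5 px per axis),
  composed as a single affine map about the image center and resampled
  bilinearly.

Pixels exposed by the transform are filled with the image's per-channel
median, a skin-tone-like fill that avoids black-corner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import Label

__all__ = ["AugmentPolicy", "oversample_balance", "random_augment", "affine_params"]


@dataclass(frozen=True)
class AugmentPolicy:
    """Ranges for the three augmentation operations."""

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    scale_x: float = 0.8
    scale_y: float = 1.0
    translation_px: tuple[int, int] = (-5, 5)
    fill: str = "median"  # or "zero"

    def __post_init__(self) -> None:
        lo, hi = self.rotation_deg
        if abs(lo + hi) > 1e-12:
            raise ValueError(f"rotation interval must be symmetric, got {self.rotation_deg}")
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scale factors must be positive")
        if self.fill not in ("median", "zero"):
            raise ValueError(f"unknown fill strategy {self.fill!r}")


def oversample_balance(
    class_counts: dict[Label, list[str]],
    seed: int = 0,
) -> list[tuple[str, bool]]:
    """Balance classes by uniform sampling with replacement.

    Every class is brought up to the size of the largest class.  All
    originals are retained (flagged ``False``); the appended duplicates
    are flagged ``True`` so online augmentation can be applied to them.
    """
    if not class_counts:
        raise ValueError("no classes given")
    for label, ids in class_counts.items():
        if not ids:
            raise ValueError(f"class {label} has no samples; cannot oversample")
    target = max(len(ids) for ids in class_counts.values())
    rng = np.random.default_rng(seed)
    out: list[tuple[str, bool]] = []
    for label in sorted(class_counts, key=lambda l: l.value):
        ids = class_counts[label]
        out.extend((i, False) for i in ids)
        deficit = target - len(ids)
        if deficit > 0:
            picks = rng.integers(0, len(ids), size=deficit)
            out.extend((ids[int(p)], True) for p in picks)
    return out


def affine_params(policy: AugmentPolicy, rng: np.random.Generator):
    """Draw (angle_deg, sx, sy, tx, ty) from the policy intervals."""
    angle = rng.uniform(*policy.rotation_deg)
    sx_lo, sx_hi = min(policy.scale_x, 1.0), max(policy.scale_x, 1.0)
    sy_lo, sy_hi = min(policy.scale_y, 1.0), max(policy.scale_y, 1.0)
    sx = rng.uniform(sx_lo, sx_hi) if sx_hi > sx_lo else sx_lo
    sy = rng.uniform(sy_lo, sy_hi) if sy_hi > sy_lo else sy_lo
    t_lo, t_hi = policy.translation_px
    tx = int(rng.integers(t_lo, t_hi + 1))
    ty = int(rng.integers(t_lo, t_hi + 1))
    return angle, sx, sy, tx, ty


def apply_affine(
    pixels: np.ndarray,
    angle_deg: float,
    sx: float,
    sy: float,
    tx: float,
    ty: float,
    fill: str = "median",
) -> np.ndarray:
    """Rotate/scale/translate about the image center, bilinear resample.

    The forward map sends a source pixel p to ``C + t + R S (p - C)``
    (x = column, y = row, rotation matrix in that frame); resampling
    evaluates the inverse map on the output grid.
    """
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected HxWx3 array, got shape {px.shape}")
    h, w = px.shape[:2]
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # inverse in (x, y): S^-1 R^-1
    a, b = c / sx, s / sx
    cc, d = -s / sy, c / sy
    # same map in (row, col) order for ndimage
    m_rc = np.array([[d, cc], [b, a]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([ty, tx], dtype=np.float64)
    offset = center - m_rc @ (center + shift)

    out = np.empty_like(px)
    work = px.astype(np.float64)
    for ch in range(3):
        cval = float(np.median(work[..., ch])) if fill == "median" else 0.0
        res = ndimage.affine_transform(
            work[..., ch], m_rc, offset=offset, order=1, mode="constant", cval=cval
        )
        if np.issubdtype(px.dtype, np.integer):
            res = np.clip(np.rint(res), 0, 255)
        out[..., ch] = res.astype(px.dtype)
    return out


def random_augment(
    pixels: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """One random draw from the policy applied as a single affine map."""
    angle, sx, sy, tx, ty = affine_params(policy, rng)
    return apply_affine(pixels, angle, sx, sy, tx, ty, fill=policy.fill)
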