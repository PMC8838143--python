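"""Geometric standardization: center square crop and bilinear resize.

Every image entering the network is cropped to a square around its
geometric center (lesions are centered in dermoscopic framing) and
rescaled to 128 x 128 x 3 by bilinear interpolation.  The bilinear
convention is half-pixel-centered (``align_corners=false``): output
pixel o samples the source at ``(o + 0.5) * S / target - 0.5``.
Frameworks differ on this point, so it is fixed here explicitly; all
numeric contracts in the tests assume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PreprocessPolicy", "center_crop_square", "resize_bilinear", "standardize"]


@dataclass(frozen=True)
class PreprocessPolicy:
    """Crop/resize policy; only center-square crop + bilinear resize exist."""

    target_size: int = 128

    def __post_init__(self) -> None:
        if self.target_size < 8:
            raise ValueError(f"target_size must be >= 8, got {self.target_size}")


def center_crop_square(pixels: np.ndarray) -> np.ndarray:
    """Crop H x W x C to S x S x C with S = min(H, W), centered.

    For an odd margin the extra pixel is dropped from the trailing edge
    (offset = floor((dim - S) / 2)).
    """
    px = np.asarray(pixels)
    if px.ndim not in (2, 3):
        raise ValueError(f"expected HxW or HxWxC array, got shape {px.shape}")
    h, w = px.shape[:2]
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return px[top : top + s, left : left + s]


def _interp_axis(size: int, target: int, dtype=np.float64):
    """Half-pixel source coordinates: lower index, upper index, upper weight."""
    coords = (np.arange(target, dtype=dtype) + 0.5) * (size / target) - 0.5
    coords = np.clip(coords, 0.0, size - 1.0)
    lo = np.floor(coords).astype(np.intp)
    hi = np.minimum(lo + 1, size - 1)
    w_hi = coords - lo
    return lo, hi, w_hi


def resize_bilinear(pixels: np.ndarray, target: int) -> np.ndarray:
    """Resize an image (HxW or HxWxC) to target x target, bilinearly.

    Pure sampling interpolation: constants are preserved exactly and the
    output range never exceeds the input range.  Resizing to the input's
    own size is the identity, so the operation is idempotent.
    """
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    px = np.asarray(pixels)
    if px.ndim not in (2, 3):
        raise ValueError(f"expected HxW or HxWxC array, got shape {px.shape}")
    h, w = px.shape[:2]
    if h == target and w == target:
        return px.copy()
    work = px.astype(np.float64, copy=False)
    ylo, yhi, wy = _interp_axis(h, target)
    xlo, xhi, wx = _interp_axis(w, target)
    if px.ndim == 3:
        wy = wy[:, None, None]
        wx = wx[None, :, None]
    else:
        wy = wy[:, None]
        wx = wx[None, :]
    top = work[ylo][:, xlo] * (1 - wx) + work[ylo][:, xhi] * wx
    bot = work[yhi][:, xlo] * (1 - wx) + work[yhi][:, xhi] * wx
    out = top * (1 - wy) + bot * wy
    if np.issubdtype(px.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(px.dtype).min, np.iinfo(px.dtype).max)
        return out.astype(px.dtype)
    return out.astype(px.dtype)


def standardize(pixels: np.ndarray, policy: PreprocessPolicy = PreprocessPolicy()) -> np.ndarray:
    """Crop to square then resize to policy.target_size (the full pipeline)."""
    return resize_bilinear(center_crop_square(pixels), policy.target_size)
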