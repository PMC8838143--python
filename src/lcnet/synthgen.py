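"""Seeded generator of lesion-like dermoscopy images.

Real dermoscopic archives cannot ship with the package, so every
pipeline stage is exercised on generated images that mimic the coarse
statistics of dermoscopy: a skin-tone background with sensor noise, a
centered elliptical lesion whose darkness and boundary irregularity
separate the classes, and optional acquisition artifacts (dark hair
strokes, bright gel-bubble rings).

Class profiles (fixed, intentionally well-separated so downstream
training benchmarks are stable across seeds):

* MEL — dark brown lesion, strongly radius-perturbed boundary and
  speckled texture;
* BEN — lighter smooth-edged lesion with mild texture.

Exact duplicate copies can be injected at a configurable rate to give
the deduplication stage a sharp target: duplicates correlate at 1.0
while distinct renders stay well below the 0.99 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .dataio import ImageRecord, Label, Manifest, ManifestRow, write_manifest
from .dedupe import to_grayscale

__all__ = ["SynthSpec", "render_lesion", "generate_dataset", "save_dataset"]

#: minimum separation of class-conditional mean luma, asserted per set
MIN_LUMA_GAP = 20.0


@dataclass(frozen=True)
class SynthSpec:
    n_per_class: int = 100
    image_size: int = 192
    hair_rate: float = 0.3
    bubble_rate: float = 0.2
    duplicate_rate: float = 0.0
    imbalance: tuple[float, float] = (1.0, 1.0)  # (MEL, BEN) multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for p in (self.hair_rate, self.bubble_rate, self.duplicate_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")


def _lesion_mask(size: int, rng: np.random.Generator, irregular: bool) -> np.ndarray:
    """Soft mask of a radius-perturbed ellipse centered near the middle."""
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    r0 = size * rng.uniform(0.30, 0.34)
    n_harm = 5
    amp = rng.uniform(0, 0.15 if irregular else 0.04, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    phi = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx * rng.uniform(1.0, 1.15))  # slight ellipticity
    rb = r0 * (1 + sum(a * np.cos((k + 2) * phi + p) for k, (a, p) in enumerate(zip(amp, phase))))
    rb = np.maximum(rb, 0.4 * r0)
    return np.clip((rb - dist) / 3.0 + 0.5, 0.0, 1.0)  # ~3 px soft edge


def _draw_hair(img: np.ndarray, rng: np.random.Generator) -> None:
    """Dark quadratic-arc strokes across the frame, 1-2 px wide."""
    size = img.shape[0]
    for _ in range(rng.integers(1, 4)):
        pts = rng.uniform(0, size, size=(3, 2))
        t = np.linspace(0, 1, 4 * size)[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + (t**2) * pts[2]
        ij = np.round(curve).astype(int)
        ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < size - 1) & (ij[:, 1] >= 0) & (ij[:, 1] < size - 1)]
        color = np.array([35.0, 25.0, 20.0])
        for off in ((0, 0), (1, 0), (0, 1)):
            y, x = ij[:, 0] + off[0], ij[:, 1] + off[1]
            img[y, x] = 0.35 * img[y, x] + 0.65 * color


def _draw_bubble(img: np.ndarray, rng: np.random.Generator) -> None:
    """A bright circular highlight ring (gel bubble)."""
    size = img.shape[0]
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    radius = rng.uniform(6, 18)
    yy, xx = np.mgrid[0:size, 0:size]
    ring = np.abs(np.hypot(yy - cy, xx - cx) - radius) < 1.5
    img[ring] = np.minimum(img[ring] + 55.0, 255.0)


def render_lesion(label: Label, spec: SynthSpec, rng: np.random.Generator) -> ImageRecord:
    """Render one lesion image; deterministic for a given generator state."""
    size = spec.image_size
    base = np.array(
        [rng.uniform(202, 218), rng.uniform(162, 178), rng.uniform(142, 158)]
    )
    img = base[None, None, :] + rng.normal(0, 5, size=(size, size, 3))

    if label == Label.MEL:
        color = np.array([45.0, 28.0, 22.0]) + rng.uniform(-10, 10, size=3)
        texture = rng.normal(0, 12, size=(size, size, 3))
    else:
        color = np.array([175.0, 125.0, 105.0]) + rng.uniform(-10, 10, size=3)
        texture = rng.normal(0, 4, size=(size, size, 3))
    alpha = _lesion_mask(size, rng, irregular=label == Label.MEL)[..., None]
    lesion = color[None, None, :] + texture
    if label == Label.MEL:  # dark speckles inside the lesion
        for _ in range(int(rng.integers(25, 45))):
            sy, sx = rng.uniform(0, size, size=2)
            sr = rng.uniform(1, 3)
            yy, xx = np.mgrid[0:size, 0:size]
            spot = np.hypot(yy - sy, xx - sx) < sr
            lesion[spot] -= rng.uniform(20, 60)
    img = alpha * lesion + (1 - alpha) * img

    if rng.uniform() < spec.hair_rate:
        _draw_hair(img, rng)
    if rng.uniform() < spec.bubble_rate:
        _draw_bubble(img, rng)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageRecord(id="", pixels=pixels, label=label)


def generate_dataset(spec: SynthSpec) -> tuple[list[ImageRecord], Manifest]:
    """Render the full set: per-class images plus exact duplicate copies.

    Duplicates (``round(duplicate_rate * n_base)`` of them) are bit-exact
    copies of distinct base images, appended after the originals, so a
    greedy duplicate scan must remove exactly them.  The class profiles'
    separability contract — class-conditional mean luma differing by at
    least 20 intensity units — is asserted on every generated set.
    """
    rng = np.random.default_rng(spec.seed)
    n_mel = round(spec.n_per_class * spec.imbalance[0])
    n_ben = round(spec.n_per_class * spec.imbalance[1])
    records: list[ImageRecord] = []
    for label, count in ((Label.MEL, n_mel), (Label.BEN, n_ben)):
        for i in range(count):
            rec = render_lesion(label, spec, rng)
            rec.id = f"{label.value}_{i:04d}"
            records.append(rec)

    n_dup = round(spec.duplicate_rate * len(records))
    if n_dup > 0:
        sources = rng.choice(len(records), size=n_dup, replace=False)
        for k, src in enumerate(sorted(int(s) for s in sources)):
            orig = records[src]
            records.append(
                ImageRecord(
                    id=f"dup_{k:03d}_{orig.id}",
                    pixels=orig.pixels.copy(),
                    label=orig.label,
                )
            )

    luma = {
        lab: float(np.mean([to_grayscale(r.pixels).mean() for r in records if r.label == lab]))
        for lab in (Label.MEL, Label.BEN)
    }
    gap = abs(luma[Label.MEL] - luma[Label.BEN])
    if gap < MIN_LUMA_GAP:
        raise AssertionError(
            f"class luma separation {gap:.1f} below contract {MIN_LUMA_GAP}"
        )

    manifest = Manifest(
        [ManifestRow(id=r.id, path=f"{r.id}.png", label=r.label) for r in records]
    )
    return records, manifest


def save_dataset(
    records: list[ImageRecord],
    manifest: Manifest,
    out_dir: str | Path,
) -> Path:
    """Write PNGs and the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, row in zip(records, manifest.records):
        img_path = out_dir / row.path
        Image.fromarray(rec.pixels).save(img_path)
        rows.append(ManifestRow(id=row.id, path=str(img_path), label=row.label, split=row.split))
    manifest_path = out_dir / "manifest.csv"
    write_manifest(Manifest(rows), manifest_path)
    return manifest_path
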