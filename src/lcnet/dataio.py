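"""Dataset manifests, image reading and stratified splitting.

A dataset is described by a CSV manifest with columns
``image_path,label[,split]``.  Labels are binary: ``MEL`` (melanoma,
the positive class) vs ``BEN`` (benign).  The nevus (``NV``) and
seborrheic-keratosis (``SK``) benign subtypes are not accepted raw; they
can be folded into ``BEN`` with ``map_benign=True`` before validation.

Splitting is stratified per class at 70/10/20 (train/validation/test):
within each class the validation and test counts are round-half-up of
the fraction times the class size, and the remainder goes to train.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Label",
    "Split",
    "ImageRecord",
    "ManifestRow",
    "Manifest",
    "ManifestError",
    "DEFAULT_FRACTIONS",
    "load_manifest",
    "write_manifest",
    "read_image",
    "split_dataset",
]

DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)

#: raw benign subtype labels folded into BEN when map_benign is on
BENIGN_SYNONYMS = frozenset({"NV", "SK", "BEN"})


class Label(str, Enum):
    """Binary lesion class; melanoma is the positive class everywhere."""

    MEL = "MEL"
    BEN = "BEN"


class Split(str, Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"
    UNASSIGNED = "unassigned"


class ManifestError(ValueError):
    """Raised for malformed manifests (bad header, unknown label...)."""


@dataclass
class ImageRecord:
    """One sample: identifier, H x W x 3 8-bit pixels, label, split tag."""

    id: str
    pixels: np.ndarray
    label: Label
    split: Split = Split.UNASSIGNED

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"record {self.id!r}: pixels must be HxWx3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"record {self.id!r}: empty image")
        self.pixels = px


@dataclass(frozen=True)
class ManifestRow:
    id: str
    path: str
    label: Label
    split: Split = Split.UNASSIGNED


@dataclass
class Manifest:
    """Ordered collection of (id, path, label, split) rows."""

    records: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ManifestError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self, split: Split | None = None) -> dict[Label, int]:
        """Per-label record counts, optionally restricted to one split."""
        counts = {Label.MEL: 0, Label.BEN: 0}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.label] += 1
        return counts

    def subset(self, split: Split) -> "Manifest":
        return Manifest([r for r in self.records if r.split == split])


def _parse_label(raw: str, row_num: int, map_benign: bool) -> Label:
    name = raw.strip().upper()
    if map_benign and name in BENIGN_SYNONYMS:
        name = "BEN"
    try:
        return Label(name)
    except ValueError:
        raise ManifestError(
            f"row {row_num}: unknown label {raw!r} (expected MEL or BEN; "
            f"use map_benign to fold NV/SK into BEN)"
        ) from None


def load_manifest(path: str | Path, *, map_benign: bool = False) -> Manifest:
    """Read a manifest CSV (header ``image_path,label[,split]``).

    Rows with labels other than MEL/BEN raise :class:`ManifestError`
    naming the offending row; a missing ``split`` column leaves every
    record unassigned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    records: list[ManifestRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError(f"{path}: empty file, expected a CSV header")
        cols = [c.strip() for c in reader.fieldnames]
        if "image_path" not in cols or "label" not in cols:
            raise ManifestError(
                f"{path}: header must contain image_path,label (got {cols})"
            )
        has_split = "split" in cols
        for row_num, row in enumerate(reader, start=2):
            img_path = (row["image_path"] or "").strip()
            if not img_path:
                raise ManifestError(f"row {row_num}: empty image_path")
            label = _parse_label(row["label"] or "", row_num, map_benign)
            split = Split.UNASSIGNED
            if has_split and (row.get("split") or "").strip():
                try:
                    split = Split(row["split"].strip().lower())
                except ValueError:
                    raise ManifestError(
                        f"row {row_num}: unknown split {row['split']!r}"
                    ) from None
            records.append(ManifestRow(id=img_path, path=img_path, label=label, split=split))
    return Manifest(records)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV with columns image_path,label,split."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "label", "split"])
        for r in manifest.records:
            split = "" if r.split == Split.UNASSIGNED else r.split.value
            writer.writerow([r.path, r.label.value, split])


def read_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG into an H x W x 3 uint8 array.

    Grayscale sources are replicated across the three channels; an
    alpha channel is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable / truncated file
        raise OSError(f"cannot decode image {path}: {exc}") from exc


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    manifest: Manifest,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> Manifest:
    """Assign train/val/test splits, stratified per class.

    Within each class of size n, the validation and test sets get
    round-half-up(fraction * n) records and the remainder goes to
    train, so 100 records split 70/10/20 exactly.  Membership is a
    seeded uniform shuffle; the same seed reproduces the same split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(r.split != Split.UNASSIGNED for r in manifest.records):
        raise ValueError("split_dataset expects an unassigned manifest")

    _, f_val, f_test = fractions
    rng = np.random.default_rng(seed)
    assignment: dict[str, Split] = {}
    for label in (Label.MEL, Label.BEN):
        idx = [i for i, r in enumerate(manifest.records) if r.label == label]
        if not idx:
            continue
        order = rng.permutation(len(idx))
        n = len(idx)
        n_val = _round_half_up(f_val * n)
        n_test = _round_half_up(f_test * n)
        if n_val + n_test > n:
            raise ValueError(f"class {label.value}: too few records ({n}) to split")
        for k, j in enumerate(order):
            rid = manifest.records[idx[j]].id
            if k < n_val:
                assignment[rid] = Split.VAL
            elif k < n_val + n_test:
                assignment[rid] = Split.TEST
            else:
                assignment[rid] = Split.TRAIN
    return Manifest([replace(r, split=assignment.get(r.id, r.split)) for r in manifest.records])
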