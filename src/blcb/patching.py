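"""Per-pixel patch bookkeeping.

Pixel classification treats every pixel of a fundus image as the center
of a fixed-size window (64x64 by default). This module defines the
window geometry, the reflect padding that makes every pixel a valid
center, and the enumeration of per-pixel patch records with their patch
means. Records are held column-oriented in a :class:`PatchTable` so a
whole image's worth (hundreds of thousands of pixels) stays cheap;
windows themselves are materialised on demand, never all at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Category",
    "PatchGeometry",
    "PatchRecord",
    "PatchTable",
    "pad_for_patches",
    "extract_window",
    "patch_means",
    "enumerate_patches",
]


class Category(IntEnum):
    """Patch population a record belongs to."""

    UNSET = -1
    FULL_BG = 0      # window mean intensity below the background threshold
    PARTIAL_BG = 1   # non-vessel center inside the illuminated field
    VESSEL = 2
    THICK = 3        # vessel record whose center survives morphological opening
    THIN = 4


@dataclass(frozen=True)
class PatchGeometry:
    """Window geometry for per-pixel patches.

    An even ``patch_size`` has no exact center pixel; the convention here
    places the focal pixel at local index ``(patch_size // 2,) * 2``,
    which forces asymmetric padding: ``size // 2`` on top/left and
    ``size - size // 2 - 1`` on bottom/right.
    """

    patch_size: int = 64

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be at least 2")

    @property
    def center_offset(self) -> tuple[int, int]:
        c = self.patch_size // 2
        return (c, c)

    @property
    def pad_before(self) -> int:
        return self.patch_size // 2

    @property
    def pad_after(self) -> int:
        return self.patch_size - self.patch_size // 2 - 1


@dataclass(frozen=True, slots=True)
class PatchRecord:
    """One per-pixel training unit.

    ``center`` is (row, col) in the unpadded image; ``pm_image`` and
    ``pm_gt`` are the means of the image and ground-truth windows around
    it; ``label`` is the ground-truth value at the center itself.
    """

    center: tuple[int, int]
    label: int
    pm_image: float
    pm_gt: float
    category: Category = Category.UNSET
    image_id: int = 0


class PatchTable(Sequence):
    """Column-oriented, immutable-by-convention sequence of PatchRecord."""

    __slots__ = ("rows", "cols", "labels", "pm_image", "pm_gt", "category", "image_id")

    def __init__(self, rows, cols, labels, pm_image, pm_gt, category=None, image_id=None):
        n = len(rows)
        self.rows = np.asarray(rows, dtype=np.int32)
        self.cols = np.asarray(cols, dtype=np.int32)
        self.labels = np.asarray(labels, dtype=np.int8)
        self.pm_image = np.asarray(pm_image, dtype=np.float64)
        self.pm_gt = np.asarray(pm_gt, dtype=np.float64)
        self.category = (
            np.full(n, Category.UNSET, dtype=np.int8)
            if category is None else np.asarray(category, dtype=np.int8)
        )
        self.image_id = (
            np.zeros(n, dtype=np.int32)
            if image_id is None else np.asarray(image_id, dtype=np.int32)
        )
        lengths = {len(a) for a in (self.rows, self.cols, self.labels, self.pm_image,
                                    self.pm_gt, self.category, self.image_id)}
        if len(lengths) != 1:
            raise ValueError("column length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            if i < 0:
                i += len(self)
            return PatchRecord(
                center=(int(self.rows[i]), int(self.cols[i])),
                label=int(self.labels[i]),
                pm_image=float(self.pm_image[i]),
                pm_gt=float(self.pm_gt[i]),
                category=Category(int(self.category[i])),
                image_id=int(self.image_id[i]),
            )
        return self.take(np.arange(len(self))[i])

    def __iter__(self) -> Iterator[PatchRecord]:
        for i in range(len(self)):
            yield self[i]

    def take(self, idx) -> "PatchTable":
        idx = np.asarray(idx)
        return PatchTable(
            self.rows[idx], self.cols[idx], self.labels[idx],
            self.pm_image[idx], self.pm_gt[idx],
            self.category[idx], self.image_id[idx],
        )

    @staticmethod
    def concat(tables: Sequence["PatchTable"]) -> "PatchTable":
        return PatchTable(
            np.concatenate([t.rows for t in tables]),
            np.concatenate([t.cols for t in tables]),
            np.concatenate([t.labels for t in tables]),
            np.concatenate([t.pm_image for t in tables]),
            np.concatenate([t.pm_gt for t in tables]),
            np.concatenate([t.category for t in tables]),
            np.concatenate([t.image_id for t in tables]),
        )

    def keys(self) -> set[tuple[int, int, int]]:
        """(image_id, row, col) identity of every record."""
        return set(zip(self.image_id.tolist(), self.rows.tolist(), self.cols.tolist()))


def pad_for_patches(img: np.ndarray, geom: PatchGeometry = PatchGeometry()) -> np.ndarray:
    """Reflect-pad so every pixel owns a full window.

    Mirror padding without repeating the edge pixel; for the default
    64-pixel patches the pads are 32 (top/left) and 31 (bottom/right),
    so the window of center ``(i, j)`` is ``padded[i:i+64, j:j+64]``
    with the center at local offset (32, 32).
    """
    img = np.asarray(img)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError(f"need a 2-D image at least 2 px per side, got {img.shape}")
    return np.pad(img, ((geom.pad_before, geom.pad_after),) * 2, mode="reflect")


def extract_window(
    padded: np.ndarray, center: tuple[int, int], geom: PatchGeometry = PatchGeometry()
) -> np.ndarray:
    """Window of ``padded`` whose local center equals the original pixel ``center``."""
    i, j = center
    ps = geom.patch_size
    h = padded.shape[0] - ps + 1
    w = padded.shape[1] - ps + 1
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"center {center} outside unpadded bounds ({h}, {w})")
    return padded[i:i + ps, j:j + ps]


def patch_means(window: np.ndarray, gt_window: np.ndarray) -> tuple[float, float]:
    """Arithmetic means of an image window and its ground-truth window."""
    window = np.asarray(window)
    gt_window = np.asarray(gt_window)
    if window.shape != gt_window.shape:
        raise ValueError("window shapes differ")
    return float(window.mean()), float(gt_window.mean())


def _window_means(padded: np.ndarray, ps: int) -> np.ndarray:
    """Mean of every ps x ps window of ``padded`` via an integral image."""
    s = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=s[1:, 1:])
    sums = s[ps:, ps:] - s[ps:, :-ps] - s[:-ps, ps:] + s[:-ps, :-ps]
    return sums / (ps * ps)


def enumerate_patches(
    img: np.ndarray,
    gt: np.ndarray,
    geom: PatchGeometry = PatchGeometry(),
    image_id: int = 0,
) -> PatchTable:
    """One patch record per pixel, in row-major order.

    The record's label is the ground-truth value at its center; patch
    means are computed over the reflect-padded windows without ever
    materialising them (integral-image sliding sums).
    """
    img = np.asarray(img)
    gt = np.asarray(gt)
    if img.shape != gt.shape:
        raise ValueError(f"image {img.shape} and ground truth {gt.shape} differ")
    h, w = img.shape
    pm_img = _window_means(pad_for_patches(img, geom), geom.patch_size)
    pm_gt = _window_means(pad_for_patches(gt.astype(np.float64), geom), geom.patch_size)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return PatchTable(
        rows=rr.ravel(), cols=cc.ravel(),
        labels=(gt.ravel() > 0).astype(np.int8),
        pm_image=np.clip(pm_img.ravel(), 0.0, 1.0),
        pm_gt=np.clip(pm_gt.ravel(), 0.0, 1.0),
        image_id=np.full(h * w, image_id, dtype=np.int32),
    )
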