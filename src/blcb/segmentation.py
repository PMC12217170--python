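"""Whole-image segmentation from a trained patch classifier.

Every pixel of a preprocessed image is scored by the classifier on the
window centered at it; the scores are reassembled into a probability
map of the image's shape, thresholded, and optionally cleaned up by a
morphological erosion. The probability map is kept alongside the binary
mask because ROC analysis needs continuous scores.

Any object with a ``predict_proba(windows) -> probabilities`` method
over ``(N, patch_size, patch_size)`` windows can act as the classifier,
so oracle stand-ins are usable wherever the CNN is.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .patching import PatchGeometry, pad_for_patches

__all__ = [
    "segment",
    "predict_at",
    "binarize",
    "erode_mask",
    "CROSS_SELEM",
]

# default post-processing structuring element: 3x3 cross
CROSS_SELEM = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def predict_at(
    model,
    img: np.ndarray,
    centers: tuple[np.ndarray, np.ndarray],
    geom: PatchGeometry = PatchGeometry(),
    batch_size: int = 512,
) -> np.ndarray:
    """Vessel probability at selected pixel centers.

    ``centers`` is a pair of (rows, cols) index arrays into the unpadded
    image. Windows are gathered from the reflect-padded image in batches
    so memory stays bounded.
    """
    rows = np.asarray(centers[0], dtype=np.intp)
    cols = np.asarray(centers[1], dtype=np.intp)
    if rows.min(initial=0) < 0 or rows.max(initial=-1) >= img.shape[0] \
            or cols.min(initial=0) < 0 or cols.max(initial=-1) >= img.shape[1]:
        raise ValueError("center outside image bounds")
    padded = pad_for_patches(img, geom)
    win = sliding_window_view(padded, (geom.patch_size, geom.patch_size))
    out = np.empty(len(rows), dtype=np.float64)
    for start in range(0, len(rows), batch_size):
        sl = slice(start, start + batch_size)
        block = np.ascontiguousarray(win[rows[sl], cols[sl]], dtype=np.float32)
        out[sl] = model.predict_proba(block)
    return out


def segment(
    model,
    img: np.ndarray,
    geom: PatchGeometry = PatchGeometry(),
    batch_rows: int = 4,
) -> np.ndarray:
    """Dense probability map: one classifier call per pixel.

    Evaluates the window around every pixel, ``batch_rows`` image rows
    at a time, and returns a map with the image's dimensions. Model
    input size must match the patch geometry.
    """
    size = getattr(getattr(model, "config", None), "input_size", None)
    if size is not None and size != geom.patch_size:
        raise ValueError(
            f"model input size {size} != patch size {geom.patch_size}"
        )
    img = np.asarray(img)
    h, w = img.shape
    padded = pad_for_patches(img, geom)
    win = sliding_window_view(padded, (geom.patch_size, geom.patch_size))
    pmap = np.empty((h, w), dtype=np.float64)
    for r0 in range(0, h, batch_rows):
        r1 = min(r0 + batch_rows, h)
        block = np.ascontiguousarray(win[r0:r1], dtype=np.float32)
        probs = model.predict_proba(block.reshape(-1, geom.patch_size, geom.patch_size))
        pmap[r0:r1] = probs.reshape(r1 - r0, w)
    return pmap


def binarize(pmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) count as vessel."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(pmap) >= threshold).astype(np.uint8)


def erode_mask(
    mask: np.ndarray,
    selem: np.ndarray | None = None,
    iterations: int = 1,
) -> np.ndarray:
    """Morphological erosion with zero-padded borders (noise removal).

    Default structuring element is a 3x3 cross, one iteration. Erosion
    is anti-extensive: the output is a subset of the input.
    """
    if selem is None:
        selem = CROSS_SELEM
    out = ndimage.binary_erosion(
        np.asarray(mask) > 0, structure=selem, iterations=iterations, border_value=0
    )
    return out.astype(np.uint8)
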