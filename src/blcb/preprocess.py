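"""Fundus-image preprocessing.

Raw RGB fundus photographs are reduced to a single contrast-enhanced
channel before patch extraction. The green channel carries the highest
vessel/background contrast of the three, and is successively passed
through global contrast normalisation (GCN), contrast-limited adaptive
histogram equalisation (CLAHE) and a gamma correction. Every stage
preserves image dimensions and the pipeline output lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = [
    "PreprocessParams",
    "extract_green",
    "global_contrast_normalize",
    "clahe_enhance",
    "gamma_correct",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing pipeline.

    Attributes
    ----------
    gcn_scale : float
        Multiplier ``s`` applied after centering, before rescale.
    gcn_lambda : float
        Variance regulariser ``lambda`` inside the square root.
    gcn_floor : float
        Lower bound ``eps`` on the normaliser; makes constant images safe.
    clahe_clip : float
        CLAHE clip limit in histogram-count units relative to a uniform
        histogram (OpenCV convention); internally divided by the number
        of gray bins for :func:`skimage.exposure.equalize_adapthist`.
    clahe_tiles : tuple of int
        Contextual tile grid (rows, cols).
    gamma : float
        Exponent of the final power-law correction; must be positive.
    """

    gcn_scale: float = 1.0
    gcn_lambda: float = 1e-8
    gcn_floor: float = 1e-8
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma: float = 1.2

    _CLAHE_NBINS = 256


def extract_green(raw: np.ndarray) -> np.ndarray:
    """Return the green channel of an RGB image scaled to [0, 1].

    ``raw`` must be an ``(H, W, 3)`` array in RGB channel order with
    8-bit-style values in [0, 255].
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {raw.shape}")
    return raw[:, :, 1].astype(np.float64) / 255.0


def global_contrast_normalize(
    img: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Global contrast normalisation followed by a min-max rescale to [0, 1].

    The whole image is centered and divided by a regularised standard
    deviation, ``s * (x - mean) / max(eps, sqrt(lambda + var))`` with the
    population variance, then rescaled to [0, 1] so the next stage
    receives a valid intensity range. A constant image maps to zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    centered = img - img.mean()
    norm = max(params.gcn_floor, np.sqrt(params.gcn_lambda + img.var()))
    out = params.gcn_scale * centered / norm
    lo, hi = out.min(), out.max()
    if hi - lo <= 0.0:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def clahe_enhance(
    img: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] image."""
    img = np.asarray(img, dtype=np.float64)
    tr, tc = params.clahe_tiles
    h, w = img.shape
    if tr > h or tc > w:
        raise ValueError(
            f"tile grid {params.clahe_tiles} larger than image {img.shape}"
        )
    if img.size == 0 or img.max() - img.min() == 0.0:
        # flat histogram: equalisation is the identity (the underlying
        # library would rescale a constant image to all-ones)
        return np.clip(img, 0.0, 1.0)
    kernel = (max(1, h // tr), max(1, w // tc))
    clip = params.clahe_clip / params._CLAHE_NBINS
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel, clip_limit=clip,
        nbins=params._CLAHE_NBINS,
    )
    return np.clip(out, 0.0, 1.0)


def gamma_correct(
    img: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Elementwise power transform ``x ** gamma`` of a [0, 1] image."""
    if params.gamma <= 0:
        raise ValueError(f"gamma must be positive, got {params.gamma}")
    return np.power(np.asarray(img, dtype=np.float64), params.gamma)


def preprocess(
    raw: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Full pipeline: green channel -> GCN -> CLAHE -> gamma.

    Deterministic: identical input and parameters give bit-identical
    output. Returns a float image in [0, 1] of the input's height/width.
    """
    img = extract_green(raw)
    img = global_contrast_normalize(img, params)
    img = clahe_enhance(img, params)
    return gamma_correct(img, params)
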