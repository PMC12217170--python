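"""Bi-level class balancing of per-pixel training patches.

Vessel pixels are a small minority of a fundus image, and thin-vessel
pixels a minority within that minority; training on the raw pixel
population biases a classifier toward background and thick vessels.
Balancing is done by seeded random undersampling at two levels:

* Level I (inter-class): keep every vessel patch, and undersample the
  non-vessel patches to the same count, drawing a fixed proportion
  ``p`` (default 0.9) from partial-background patches (inside the
  illuminated field) and ``1 - p`` from full-background patches (the
  near-black surround).
* Level II (intra-class): first split vessel patches into thick and
  thin using morphological opening of the ground truth, undersample the
  thick side to ``r`` times the thin count, and then rebalance the
  background against the reduced vessel set exactly as in Level I.

All sampling is without replacement from deterministically ordered
catalogs with a single seeded generator per call, so a balanced set is
fully reproducible from (catalog, parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .patching import Category, PatchGeometry, PatchTable, enumerate_patches

__all__ = [
    "BalanceParams",
    "PatchCatalog",
    "ThicknessMasks",
    "BalanceCounts",
    "BalancedSet",
    "EmptyClassError",
    "categorize",
    "merge_catalogs",
    "level1_balance",
    "segregate_thickness",
    "split_vessel_patches",
    "level2_balance",
]

logger = logging.getLogger(__name__)


class EmptyClassError(ValueError):
    """Raised when balancing is asked for but the vessel class is empty."""


@dataclass(frozen=True)
class BalanceParams:
    """Knobs of the two balancing levels.

    ``t`` is the background threshold on the window mean intensity of
    the preprocessed image: windows darker than ``t`` count as full
    background. ``v`` is only consulted in ``vessel_mode='patch-mean'``,
    where a record is a vessel patch iff its ground-truth window mean is
    at least ``v``; the default mode labels by the center pixel.
    """

    v: float = 0.5 / (64 * 64)
    t: float = 0.10
    p: float = 0.9
    r: float = 1.0
    seed: int = 0
    vessel_mode: str = "center-pixel"  # or "patch-mean"

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not (0.0 <= self.t <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError("thresholds t, v must lie in [0, 1]")
        if self.vessel_mode not in ("center-pixel", "patch-mean"):
            raise ValueError(f"unknown vessel_mode {self.vessel_mode!r}")


@dataclass
class PatchCatalog:
    """Disjoint patch populations of one or more images.

    ``alpha`` (vessel), ``beta`` (partial background) and ``gamma_full``
    (full background) partition all pixels; ``thick``/``thin`` partition
    ``alpha`` once a thickness split has been applied.
    """

    alpha: PatchTable
    beta: PatchTable
    gamma_full: PatchTable
    thick: PatchTable | None = None
    thin: PatchTable | None = None
    params: BalanceParams | None = None


@dataclass(frozen=True)
class ThicknessMasks:
    """Thick/thin decomposition of a ground-truth mask.

    ``thick`` is the morphological opening of the ground truth;
    ``thin`` is the set difference. They are disjoint and their union
    is the ground truth.
    """

    thick: np.ndarray
    thin: np.ndarray


class BalanceCounts(NamedTuple):
    n_vessel: int
    n_thick: int
    n_thin: int
    y: int       # partial-background picks
    z: int       # full-background picks


@dataclass(frozen=True)
class BalancedSet:
    """A balanced training list with full provenance."""

    records: PatchTable
    counts: BalanceCounts
    level: int
    seed: int
    params: BalanceParams


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def categorize(
    img: np.ndarray,
    gt: np.ndarray,
    params: BalanceParams = BalanceParams(),
    geom: PatchGeometry = PatchGeometry(),
    image_id: int = 0,
) -> PatchCatalog:
    """Assign every pixel's patch to vessel / partial / full background.

    A record is a vessel patch if its center ground-truth pixel is set
    (default mode) or its ground-truth window mean reaches ``v``
    (patch-mean mode). Non-vessel records with window mean intensity at
    least ``t`` are partial background; the rest are full background.
    """
    table = enumerate_patches(img, gt, geom, image_id=image_id)
    if params.vessel_mode == "patch-mean":
        vessel = table.pm_gt >= params.v
    else:
        vessel = table.labels == 1
    partial = ~vessel & (table.pm_image >= params.t)
    full = ~vessel & ~partial
    table.category[vessel] = Category.VESSEL
    table.category[partial] = Category.PARTIAL_BG
    table.category[full] = Category.FULL_BG
    idx = np.arange(len(table))
    return PatchCatalog(
        alpha=table.take(idx[vessel]),
        beta=table.take(idx[partial]),
        gamma_full=table.take(idx[full]),
        params=params,
    )


def merge_catalogs(catalogs: Sequence[PatchCatalog]) -> PatchCatalog:
    """Pool the populations of several images into one catalog."""
    def cat(parts):
        return PatchTable.concat(parts) if parts else None
    thick = [c.thick for c in catalogs if c.thick is not None]
    thin = [c.thin for c in catalogs if c.thin is not None]
    return PatchCatalog(
        alpha=PatchTable.concat([c.alpha for c in catalogs]),
        beta=PatchTable.concat([c.beta for c in catalogs]),
        gamma_full=PatchTable.concat([c.gamma_full for c in catalogs]),
        thick=cat(thick) if len(thick) == len(catalogs) else None,
        thin=cat(thin) if len(thin) == len(catalogs) else None,
        params=catalogs[0].params,
    )


def _sample(table: PatchTable, n: int, rng: np.random.Generator) -> PatchTable:
    idx = rng.choice(len(table), size=n, replace=False)
    return table.take(idx)


def _background_quota(
    n_vessel: int, n_beta: int, n_gamma: int, p: float
) -> tuple[int, int]:
    """Split the non-vessel quota between beta (y) and gamma (z).

    y = round(p * n_vessel) and z the remainder; a shortfall in either
    pool moves to the other. Caller guarantees n_beta + n_gamma >= n_vessel.
    """
    y = _round_half_up(p * n_vessel)
    y = min(y, n_beta)
    z = n_vessel - y
    if z > n_gamma:
        y += z - n_gamma
        z = n_gamma
    return y, z


def _select_background(
    n_vessel: int,
    beta: PatchTable,
    gamma_full: PatchTable,
    p: float,
    rng: np.random.Generator,
) -> tuple[PatchTable, PatchTable, int, int]:
    y, z = _background_quota(n_vessel, len(beta), len(gamma_full), p)
    return _sample(beta, y, rng), _sample(gamma_full, z, rng), y, z


def level1_balance(
    catalog: PatchCatalog, params: BalanceParams = BalanceParams()
) -> BalancedSet:
    """Inter-class (vessel vs. non-vessel) balancing.

    Keeps all vessel patches and samples an equal number of non-vessel
    patches, ``round(p * n_vessel)`` from partial background and the
    remainder from full background, with documented shortfall rules:
    a deficit in one background pool moves to the other, and an overall
    background deficit subsamples the vessel side instead.
    """
    if len(catalog.alpha) == 0:
        raise EmptyClassError("no vessel patches to balance against")
    rng = np.random.default_rng(params.seed)
    alpha = catalog.alpha
    avail = len(catalog.beta) + len(catalog.gamma_full)
    if avail < len(alpha):
        logger.warning(
            "background pool (%d) smaller than vessel pool (%d); subsampling vessels",
            avail, len(alpha),
        )
        alpha = _sample(alpha, avail, rng)
    beta_sel, gamma_sel, y, z = _select_background(
        len(alpha), catalog.beta, catalog.gamma_full, params.p, rng
    )
    records = PatchTable.concat([alpha, beta_sel, gamma_sel])
    return BalancedSet(
        records=records,
        counts=BalanceCounts(len(alpha), 0, 0, y, z),
        level=1,
        seed=params.seed,
        params=params,
    )


def segregate_thickness(gt: np.ndarray, selem_radius: int = 1) -> ThicknessMasks:
    """Split a vessel mask into thick and thin by morphological opening.

    The thick mask is the opening of the ground truth with a disk of the
    given radius (erosion uses a zero-padded border, so structures
    narrower than the disk vanish); the thin mask is what the opening
    removed. Radius 1 (a 3x3 disk) removes 1-2 px wide vessels.
    """
    if selem_radius < 1:
        raise ValueError(f"selem_radius must be >= 1, got {selem_radius}")
    gt = np.asarray(gt) > 0
    thick = ndimage.binary_opening(gt, structure=disk(selem_radius))
    thin = gt & ~thick
    return ThicknessMasks(thick=thick, thin=thin)


def split_vessel_patches(
    catalog: PatchCatalog, masks: ThicknessMasks
) -> PatchCatalog:
    """Fill the catalog's thick/thin vessel populations from the masks.

    Each vessel record goes to thick or thin according to which mask its
    center pixel lies in; the two must cover all vessel records.
    """
    alpha = catalog.alpha
    in_thick = masks.thick[alpha.rows, alpha.cols]
    in_thin = masks.thin[alpha.rows, alpha.cols]
    orphan = ~(in_thick | in_thin)
    if orphan.any():
        raise ValueError(
            f"{int(orphan.sum())} vessel record(s) fall in neither thickness mask; "
            "catalog and masks disagree on the ground truth"
        )
    alpha.category[in_thick] = Category.THICK
    alpha.category[in_thin] = Category.THIN
    idx = np.arange(len(alpha))
    catalog.thick = alpha.take(idx[in_thick])
    catalog.thin = alpha.take(idx[in_thin])
    return catalog


def level2_balance(
    catalog: PatchCatalog, params: BalanceParams = BalanceParams()
) -> BalancedSet:
    """Intra-class (thick vs. thin vessel) balancing on top of Level I.

    Keeps all thin-vessel patches, samples ``min(round(r * n_thin),
    n_thick)`` thick patches, and balances the background against the
    reduced vessel set with the Level-I rules. With no thin pixels at
    all the call degrades to Level-I behaviour (logged).
    """
    if catalog.thick is None or catalog.thin is None:
        raise ValueError("catalog has no thickness split; call split_vessel_patches first")
    if len(catalog.alpha) == 0:
        raise EmptyClassError("no vessel patches to balance against")
    if len(catalog.thin) == 0:
        logger.warning("no thin-vessel patches; falling back to Level-I balancing")
        fallback = level1_balance(catalog, params)
        return BalancedSet(fallback.records, fallback.counts, 2, params.seed, params)
    rng = np.random.default_rng(params.seed)
    x = min(_round_half_up(params.r * len(catalog.thin)), len(catalog.thick))
    tp = _sample(catalog.thick, x, rng)
    vessel = PatchTable.concat([tp, catalog.thin])
    avail = len(catalog.beta) + len(catalog.gamma_full)
    n_thin = len(catalog.thin)
    if avail < len(vessel):
        logger.warning(
            "background pool (%d) smaller than balanced vessel pool (%d); "
            "subsampling vessels", avail, len(vessel),
        )
        vessel = _sample(vessel, avail, rng)
        x = int(np.sum(vessel.category == Category.THICK))
        n_thin = len(vessel) - x
    beta_sel, gamma_sel, y, z = _select_background(
        len(vessel), catalog.beta, catalog.gamma_full, params.p, rng
    )
    records = PatchTable.concat([vessel, beta_sel, gamma_sel])
    return BalancedSet(
        records=records,
        counts=BalanceCounts(len(vessel), x, n_thin, y, z),
        level=2,
        seed=params.seed,
        params=params,
    )
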