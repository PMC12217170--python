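"""Segmentation performance measures and the balancing ablation protocol.

Pixel-level sensitivity (vessel recall), specificity (background
recall), accuracy and the area under the ROC curve, optionally
restricted to a field-of-view mask; plus a controlled three-arm
experiment that trains otherwise-identical classifiers on (a) an
unbalanced uniform patch sample, (b) Level-I balanced patches and
(c) Level-II balanced patches, and compares their test metrics.

AUC is the rank-based (Mann-Whitney) statistic with half credit for
ties, which coincides with trapezoidal ROC integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .balancing import (
    BalanceParams,
    categorize,
    level1_balance,
    level2_balance,
    merge_catalogs,
    segregate_thickness,
    split_vessel_patches,
)
from .cnn import ModelConfig, TrainConfig, build_classifier, train_classifier
from .patching import Category, PatchGeometry, PatchTable, pad_for_patches
from .preprocess import PreprocessParams, preprocess
from .segmentation import predict_at
from .synth import SyntheticSample

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "se_sp_acc",
    "roc_auc",
    "evaluate_segmentation",
    "ablation_run",
    "summarize_ablation",
]

logger = logging.getLogger(__name__)


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-image (or per-arm) metric bundle.

    Metrics whose denominator is empty are ``None`` (flagged undefined)
    rather than NaN-propagated.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None
    n_pixels: int
    fov_used: bool


def _flatten_restrict(arrs, fov):
    flat = [np.asarray(a).ravel() for a in arrs]
    if fov is not None:
        keep = np.asarray(fov).ravel() > 0
        flat = [a[keep] for a in flat]
    return flat


def confusion_counts(
    pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Pixel confusion counts; vessel is the positive class."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape or (fov is not None and np.shape(fov) != gt.shape):
        raise ValueError("prediction/ground-truth/FOV dimensions differ")
    p, g = _flatten_restrict([pred > 0, gt > 0], fov)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    tn = int(np.sum(~p & ~g))
    fn = int(np.sum(~p & g))
    return ConfusionCounts(tp, fp, tn, fn)


def se_sp_acc(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """Sensitivity, specificity, accuracy; ``None`` where undefined."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total if c.total > 0 else None
    return se, sp, acc


def roc_auc(
    scores: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> float | None:
    """Rank-based AUC of continuous scores against a binary truth.

    Equivalent to the Mann-Whitney U statistic normalised by the number
    of positive-negative pairs, with tied scores counted half;
    ``None`` when only one class is present in the evaluated region.
    """
    s, g = _flatten_restrict([np.asarray(scores, dtype=np.float64),
                              np.asarray(gt) > 0], fov)
    n_pos = int(g.sum())
    n_neg = len(g) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # average ranks give ties half credit
    u = ranks[g].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_segmentation(
    pred: np.ndarray,
    gt: np.ndarray,
    pmap: np.ndarray | None = None,
    fov: np.ndarray | None = None,
) -> MetricsReport:
    """Full metric bundle for one segmented image."""
    c = confusion_counts(pred, gt, fov)
    se, sp, acc = se_sp_acc(c)
    auc = roc_auc(pmap, gt, fov) if pmap is not None else None
    return MetricsReport(se, sp, acc, auc, c.total, fov is not None)


# -- ablation protocol -------------------------------------------------


def _stratified_subsample(
    table: PatchTable, budget: int, rng: np.random.Generator
) -> PatchTable:
    """Subsample to ``budget`` records, preserving category proportions.

    Largest-remainder apportionment over categories keeps the sampled
    composition as close to the original as integer counts allow.
    """
    n = len(table)
    if budget >= n:
        return table
    cats, counts = np.unique(table.category, return_counts=True)
    exact = counts * (budget / n)
    take = np.floor(exact).astype(int)
    remainder = exact - take
    for i in np.argsort(-remainder)[: budget - take.sum()]:
        take[i] += 1
    picks = []
    idx = np.arange(n)
    for cat, k in zip(cats, take):
        pool = idx[table.category == cat]
        picks.append(rng.choice(pool, size=k, replace=False))
    return table.take(np.concatenate(picks))


def _gather_windows(
    samples: Sequence[SyntheticSample],
    imgs: list[np.ndarray],
    records: PatchTable,
    geom: PatchGeometry,
) -> np.ndarray:
    """Materialise the 64x64 training windows for a balanced set."""
    from numpy.lib.stride_tricks import sliding_window_view

    out = np.empty((len(records), geom.patch_size, geom.patch_size), dtype=np.float32)
    for img_id in np.unique(records.image_id):
        view = sliding_window_view(
            pad_for_patches(imgs[img_id], geom), (geom.patch_size, geom.patch_size)
        )
        sel = records.image_id == img_id
        out[sel] = view[records.rows[sel], records.cols[sel]]
    return out


def _eval_pixels(
    sample: SyntheticSample, cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified evaluation pixels for one test image.

    Returns (rows, cols): up to ``cap`` vessel pixels — the quota split
    evenly between thin and thick vessels so both widths are always
    represented, spare quota flowing to whichever class has pixels
    left — plus an equal number of non-vessel pixels sampled from the
    whole image.
    """
    thin_r, thin_c = np.nonzero(sample.thin_gt)
    thick_r, thick_c = np.nonzero(sample.thick_gt)
    n_thin = min(len(thin_r), max(cap // 2, cap - len(thick_r)))
    n_thick = min(len(thick_r), cap - n_thin)
    keep_thin = rng.choice(len(thin_r), size=n_thin, replace=False)
    keep_thick = rng.choice(len(thick_r), size=n_thick, replace=False)
    rows = np.concatenate([thin_r[keep_thin], thick_r[keep_thick]])
    cols = np.concatenate([thin_c[keep_thin], thick_c[keep_thick]])
    bg_r, bg_c = np.nonzero(sample.gt == 0)
    n_bg = min(len(rows), len(bg_r))
    keep = rng.choice(len(bg_r), size=n_bg, replace=False)
    return (
        np.concatenate([rows, bg_r[keep]]),
        np.concatenate([cols, bg_c[keep]]),
    )


def ablation_run(
    train_samples: Sequence[SyntheticSample],
    test_samples: Sequence[SyntheticSample],
    *,
    seeds: Sequence[int] = (0, 1, 2),
    arms: Sequence[str] = ("none", "level1", "level2"),
    model_config: ModelConfig = ModelConfig(base_filters=6, fc_sizes=(48, 24, 12)),
    train_config: TrainConfig = TrainConfig(epochs=5),
    balance_params: BalanceParams = BalanceParams(),
    preprocess_params: PreprocessParams = PreprocessParams(),
    geom: PatchGeometry = PatchGeometry(),
    selem_radius: int = 1,
    patch_budget: int = 1800,
    eval_cap: int = 600,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Three-arm balancing ablation on synthetic data.

    All arms share the model and training configuration and an
    identical patch budget; they differ only in how training patches
    are selected. The "none" arm subsamples the raw pixel population
    uniformly (preserving natural class proportions); "level1" and
    "level2" apply the corresponding balancing level and are then
    capped to the same budget by stratified subsampling. Test metrics
    are computed on a stratified pixel sample per test image (all thin
    vessel pixels kept up to ``eval_cap``), including thin-vessel
    sensitivity. Returns one row per (seed, arm, image) plus an
    average row per (seed, arm).
    """
    train_imgs = [preprocess(s.rgb, preprocess_params) for s in train_samples]
    test_imgs = [preprocess(s.rgb, preprocess_params) for s in test_samples]

    catalogs = []
    for i, (s, img) in enumerate(zip(train_samples, train_imgs)):
        cat = categorize(img, s.gt, balance_params, geom, image_id=i)
        masks = segregate_thickness(s.gt, selem_radius)
        catalogs.append(split_vessel_patches(cat, masks))
    catalog = merge_catalogs(catalogs)
    full_table = PatchTable.concat([catalog.alpha, catalog.beta, catalog.gamma_full])

    rows_out = []
    for seed in seeds:
        seed_rng = np.random.default_rng(seed)
        bp = replace(balance_params, seed=int(seed_rng.integers(2 ** 31 - 1)))
        arm_sets = {}
        for arm in arms:
            if arm == "none":
                arm_sets[arm] = _stratified_subsample(
                    full_table, patch_budget,
                    np.random.default_rng(bp.seed),
                )
            elif arm == "level1":
                arm_sets[arm] = _stratified_subsample(
                    level1_balance(catalog, bp).records, patch_budget,
                    np.random.default_rng(bp.seed + 1),
                )
            elif arm == "level2":
                arm_sets[arm] = _stratified_subsample(
                    level2_balance(catalog, bp).records, patch_budget,
                    np.random.default_rng(bp.seed + 2),
                )
            else:
                raise ValueError(f"unknown arm {arm!r}")
        for arm in arms:
            records = arm_sets[arm]
            windows = _gather_windows(train_samples, train_imgs, records, geom)
            model = build_classifier(model_config, seed=int(seed))
            tc = replace(train_config, seed=int(seed))
            logger.info(
                "seed %s arm %-6s: training on %d patches (%d vessel)",
                seed, arm, len(records), int(np.sum(records.labels == 1)),
            )
            train_classifier(model, windows, records.labels, tc)
            arm_rows = []
            for j, (sample, img) in enumerate(zip(test_samples, test_imgs)):
                px_rng = np.random.default_rng(10_000 + seed)
                rr, cc = _eval_pixels(sample, eval_cap, px_rng)
                probs = predict_at(model, img, (rr, cc), geom)
                truth = sample.gt[rr, cc] > 0
                thin_sel = sample.thin_gt[rr, cc] > 0
                pred = probs >= threshold
                se = float(np.mean(pred[truth])) if truth.any() else np.nan
                sp = float(np.mean(~pred[~truth])) if (~truth).any() else np.nan
                acc = float(np.mean(pred == truth))
                auc = roc_auc(probs, truth)
                thin_se = float(np.mean(pred[thin_sel])) if thin_sel.any() else np.nan
                arm_rows.append(dict(
                    seed=seed, arm=arm, image=f"test{j}",
                    se=se, sp=sp, acc=acc,
                    auc=np.nan if auc is None else auc,
                    thin_se=thin_se,
                    n_eval=len(rr), n_train=len(records),
                ))
            avg = {k: float(np.mean([r[k] for r in arm_rows]))
                   for k in ("se", "sp", "acc", "auc", "thin_se")}
            rows_out.extend(arm_rows)
            rows_out.append(dict(
                seed=seed, arm=arm, image="average", **avg,
                n_eval=sum(r["n_eval"] for r in arm_rows),
                n_train=len(records),
            ))
    return pd.DataFrame(rows_out)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per arm over seeds (average rows only)."""
    avg = table[table["image"] == "average"]
    return avg.groupby("arm")[["se", "sp", "acc", "auc", "thin_se"]].mean()
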