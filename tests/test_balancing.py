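"""Bi-level balancing: categorisation, sampling arithmetic, thickness split."""

import numpy as np
import pytest

from blcb.balancing import (
    BalanceParams,
    EmptyClassError,
    categorize,
    level1_balance,
    level2_balance,
    merge_catalogs,
    segregate_thickness,
    split_vessel_patches,
)
from blcb.patching import Category, PatchGeometry, PatchTable, enumerate_patches
from blcb.patching import extract_window, pad_for_patches


def make_table(n: int, label: int, category: Category, start: int = 0) -> PatchTable:
    """Synthetic patch table with unique centers."""
    rows = np.arange(start, start + n) // 1000
    cols = np.arange(start, start + n) % 1000
    return PatchTable(
        rows, cols,
        np.full(n, label), np.full(n, 0.5), np.full(n, float(label)),
        np.full(n, int(category)),
    )


def make_catalog(n_alpha, n_beta, n_gamma, n_thick=None, n_thin=None):
    from blcb.balancing import PatchCatalog

    if n_thick is not None:
        thick = make_table(n_thick, 1, Category.THICK, 0)
        thin = make_table(n_thin, 1, Category.THIN, n_thick)
        alpha = PatchTable.concat([thick, thin])
    else:
        thick = thin = None
        alpha = make_table(n_alpha, 1, Category.VESSEL, 0)
    return PatchCatalog(
        alpha=alpha,
        beta=make_table(n_beta, 0, Category.PARTIAL_BG, 100_000),
        gamma_full=make_table(n_gamma, 0, Category.FULL_BG, 500_000),
        thick=thick,
        thin=thin,
    )


class TestCategorize:
    def test_black_image_all_full_background(self):
        cat = categorize(np.zeros((20, 20)), np.zeros((20, 20), dtype=np.uint8))
        assert len(cat.gamma_full) == 400
        assert len(cat.alpha) == 0 and len(cat.beta) == 0

    def test_partition_covers_every_pixel(self, small_sample):
        from blcb.preprocess import preprocess

        img = preprocess(small_sample.rgb)
        cat = categorize(img, small_sample.gt)
        n = img.size
        assert len(cat.alpha) + len(cat.beta) + len(cat.gamma_full) == n
        keys = cat.alpha.keys() | cat.beta.keys() | cat.gamma_full.keys()
        assert len(keys) == n

    def test_against_per_pixel_oracle(self):
        # 32x32: bright 16-column band holding a 2-px vessel stripe
        img = np.zeros((32, 32))
        img[:, 8:24] = 0.6
        gt = np.zeros((32, 32), dtype=np.uint8)
        gt[:, 15:17] = 1
        params = BalanceParams(t=0.10)
        geom = PatchGeometry()
        cat = categorize(img, gt, params, geom)
        pi = pad_for_patches(img, geom)
        pg = pad_for_patches(gt.astype(float), geom)
        counts = {"a": 0, "b": 0, "g": 0}
        for i in range(32):
            for j in range(32):
                if gt[i, j] == 1:
                    counts["a"] += 1
                elif extract_window(pi, (i, j), geom).mean() >= params.t:
                    counts["b"] += 1
                else:
                    counts["g"] += 1
        assert (len(cat.alpha), len(cat.beta), len(cat.gamma_full)) == (
            counts["a"], counts["b"], counts["g"])

    def test_patch_mean_mode(self):
        img = np.full((20, 20), 0.5)
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt[10, 10] = 1
        params = BalanceParams(vessel_mode="patch-mean", v=0.5 / 64 ** 2)
        cat = categorize(img, gt, params)
        # every window containing the lone vessel pixel qualifies
        assert len(cat.alpha) == 400  # window covers whole 20x20 image always


class TestLevel1:
    def test_ninety_ten_arithmetic(self):
        cat = make_catalog(100, 200, 50)
        out = level1_balance(cat, BalanceParams(p=0.9, seed=1))
        assert out.counts.y == 90 and out.counts.z == 10
        assert len(out.records) == 200
        labels = out.records.labels
        assert int(np.sum(labels == 1)) == int(np.sum(labels == 0)) == 100

    def test_round_half_up_remainder(self):
        out = level1_balance(make_catalog(7, 100, 100), BalanceParams(p=0.9))
        assert out.counts.y == 6 and out.counts.z == 1

    def test_beta_shortfall_moves_to_gamma(self):
        out = level1_balance(make_catalog(10, 4, 100), BalanceParams(p=0.9))
        assert out.counts.y == 4 and out.counts.z == 6

    def test_gamma_shortfall_moves_to_beta(self):
        out = level1_balance(make_catalog(100, 500, 3), BalanceParams(p=0.9))
        assert out.counts.z == 3 and out.counts.y == 97

    def test_overall_background_deficit_subsamples_vessels(self):
        out = level1_balance(make_catalog(50, 10, 10), BalanceParams(p=0.9))
        assert out.counts.n_vessel == 20
        labels = out.records.labels
        assert int(np.sum(labels == 1)) == int(np.sum(labels == 0)) == 20

    def test_seeded_reproducibility_and_no_duplicates(self):
        cat = make_catalog(100, 2000, 400)
        a = level1_balance(cat, BalanceParams(seed=7))
        b = level1_balance(cat, BalanceParams(seed=7))
        c = level1_balance(cat, BalanceParams(seed=8))
        assert np.array_equal(a.records.rows, b.records.rows)
        assert np.array_equal(a.records.cols, b.records.cols)
        assert not np.array_equal(a.records.cols, c.records.cols)
        assert len(a.records.keys()) == len(a.records)

    def test_empty_vessel_class_rejected(self):
        with pytest.raises(EmptyClassError):
            level1_balance(make_catalog(0, 10, 10))


class TestSegregateThickness:
    @staticmethod
    def brute_force_opening(gt, selem):
        """Erosion then dilation with explicit loops, zero padding."""
        h, w = gt.shape
        offs = [(i - selem.shape[0] // 2, j - selem.shape[1] // 2)
                for i in range(selem.shape[0]) for j in range(selem.shape[1])
                if selem[i, j]]
        eroded = np.zeros_like(gt)
        for i in range(h):
            for j in range(w):
                eroded[i, j] = all(
                    0 <= i + di < h and 0 <= j + dj < w and gt[i + di, j + dj]
                    for di, dj in offs)
        dilated = np.zeros_like(gt)
        for i in range(h):
            for j in range(w):
                dilated[i, j] = any(
                    0 <= i + di < h and 0 <= j + dj < w and eroded[i + di, j + dj]
                    for di, dj in offs)
        return dilated

    def test_empty_mask(self):
        masks = segregate_thickness(np.zeros((8, 8), dtype=np.uint8))
        assert not masks.thick.any() and not masks.thin.any()

    def test_single_pixel_diagonal_is_thin(self):
        gt = np.eye(9, dtype=np.uint8)
        masks = segregate_thickness(gt, 1)
        assert not masks.thick.any()
        assert np.array_equal(masks.thin, gt.astype(bool))

    def test_toy_grid_matches_brute_force_oracle(self):
        from skimage.morphology import disk

        gt = np.zeros((11, 11), dtype=np.uint8)
        gt[2:7, 1:10] = 1        # 5-px-wide bar
        gt[9, :] = 1             # 1-px line
        masks = segregate_thickness(gt, 1)
        oracle = self.brute_force_opening(gt, disk(1))
        assert np.array_equal(masks.thick, oracle.astype(bool))
        assert np.array_equal(masks.thin, gt.astype(bool) & ~oracle.astype(bool))

    def test_partition_and_anti_extensivity(self, sample):
        masks = segregate_thickness(sample.gt, 1)
        gt = sample.gt.astype(bool)
        assert np.array_equal(masks.thick | masks.thin, gt)
        assert not (masks.thick & masks.thin).any()
        assert np.all(masks.thick <= gt)

    def test_opening_idempotent(self, sample):
        once = segregate_thickness(sample.gt, 1).thick
        twice = segregate_thickness(once.astype(np.uint8), 1).thick
        assert np.array_equal(once, twice)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            segregate_thickness(np.zeros((4, 4)), 0)


class TestSplitVesselPatches:
    def test_all_thick_when_thin_mask_empty(self):
        img = np.full((16, 16), 0.5)
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[4:12, 4:12] = 1  # 8x8 block survives opening entirely
        cat = categorize(img, gt)
        masks = segregate_thickness(gt, 1)
        cat = split_vessel_patches(cat, masks)
        assert len(cat.thin) + len(cat.thick) == len(cat.alpha)
        assert len(cat.thin) == int(masks.thin.sum())

    def test_partition_counts(self, small_sample):
        from blcb.preprocess import preprocess

        cat = categorize(preprocess(small_sample.rgb), small_sample.gt)
        cat = split_vessel_patches(cat, segregate_thickness(small_sample.gt, 1))
        assert len(cat.thick) + len(cat.thin) == len(cat.alpha)
        assert not (cat.thick.keys() & cat.thin.keys())

    def test_construction_width_agreement(self, sample_batch):
        """Opening with radius 1 recovers the generator's width classes."""
        for s in sample_batch[:2]:
            masks = segregate_thickness(s.gt, 1)
            vessel = s.gt.astype(bool)
            agree = (masks.thick[vessel] == s.thick_gt.astype(bool)[vessel]).mean()
            assert agree >= 0.9

    def test_inconsistent_masks_rejected(self):
        img = np.full((16, 16), 0.5)
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, 8] = 1
        cat = categorize(img, gt)
        masks = segregate_thickness(np.zeros_like(gt), 1)  # wrong gt
        with pytest.raises(ValueError):
            split_vessel_patches(cat, masks)


class TestLevel2:
    def test_unit_ratio_arithmetic(self):
        cat = make_catalog(None, 200, 50, n_thick=500, n_thin=50)
        out = level2_balance(cat, BalanceParams(r=1.0, p=0.9, seed=0))
        assert out.counts.n_thick == 50 and out.counts.n_thin == 50
        assert out.counts.y == 90 and out.counts.z == 10
        assert len(out.records) == 200

    def test_ratio_two(self):
        cat = make_catalog(None, 500, 100, n_thick=500, n_thin=50)
        out = level2_balance(cat, BalanceParams(r=2.0, seed=0))
        assert out.counts.n_thick == 100

    def test_thick_capped_at_available(self):
        cat = make_catalog(None, 500, 100, n_thick=30, n_thin=80)
        out = level2_balance(cat, BalanceParams(r=1.0, seed=0))
        assert out.counts.n_thick == 30
        assert out.counts.n_vessel == 110

    def test_balance_and_reproducibility(self):
        cat = make_catalog(None, 3000, 500, n_thick=400, n_thin=150)
        a = level2_balance(cat, BalanceParams(seed=3))
        b = level2_balance(cat, BalanceParams(seed=3))
        labels = a.records.labels
        assert int(np.sum(labels == 1)) == int(np.sum(labels == 0))
        assert np.array_equal(a.records.cols, b.records.cols)
        assert len(a.records.keys()) == len(a.records)

    def test_no_thin_falls_back_to_level1(self, caplog):
        cat = make_catalog(None, 500, 100, n_thick=100, n_thin=0)
        out = level2_balance(cat, BalanceParams(seed=0))
        assert out.level == 2
        assert out.counts.n_vessel == 100
        labels = out.records.labels
        assert int(np.sum(labels == 1)) == int(np.sum(labels == 0)) == 100

    def test_requires_thickness_split(self):
        with pytest.raises(ValueError):
            level2_balance(make_catalog(10, 10, 10), BalanceParams())


class TestMergeCatalogs:
    def test_pooling_preserves_counts(self, small_sample, sample):
        from blcb.preprocess import preprocess

        cats = []
        for i, s in enumerate((small_sample, sample)):
            c = categorize(preprocess(s.rgb), s.gt, image_id=i)
            cats.append(split_vessel_patches(c, segregate_thickness(s.gt, 1)))
        merged = merge_catalogs(cats)
        assert len(merged.alpha) == sum(len(c.alpha) for c in cats)
        assert len(merged.thick) == sum(len(c.thick) for c in cats)
        assert len(merged.alpha.keys()) == len(merged.alpha)


class TestBalanceParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(p=0.0), dict(p=1.5), dict(r=-1.0), dict(t=1.2),
                   dict(vessel_mode="bogus")]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BalanceParams(**kwargs)
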