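"""Segmentation stages against ground truth and hand-built morphology
fixtures exercising every stated threshold."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import measure
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse

from histospec.segmentation import (
    blue_ratio_image,
    finalize_nuclei,
    partition_epithelium,
    refine_nuclei_mask,
    segment_epithelium,
    segment_tissue,
    split_large_clusters,
    split_small_clusters,
)
from histospec.synthetic import DEFAULT_STAIN_COLORS, generate_he_image


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def bridged_dumbbell(a, b, gap, bridge_w, shape=(70, 110),
                     colors=((60, 45, 130), (75, 55, 115))):
    """Two ellipse lobes joined by a thin bridge: one low-solidity component."""
    mask = np.zeros(shape, dtype=bool)
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = (230, 150, 180)
    c1, c2 = 40, 40 + 2 * b + gap
    rr, cc = ellipse(35, c1, a, b)
    mask[rr, cc] = True
    img[rr, cc] = colors[0]
    rr, cc = ellipse(35, c2, a, b)
    mask[rr, cc] = True
    img[rr, cc] = colors[1]
    mask[35 - bridge_w // 2 : 35 + (bridge_w + 1) // 2, c1:c2] = True
    img[35 - bridge_w // 2 : 35 + (bridge_w + 1) // 2, c1:c2] = colors[0]
    return mask, img


class TestBlueRatio:
    def test_pure_blue_pixel(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (0, 0, 255)
        assert blue_ratio_image(img)[0, 0] == pytest.approx(255 / 256)

    def test_pure_white_pixel(self):
        img = np.full((1, 1, 3), 255, dtype=np.uint8)
        assert blue_ratio_image(img)[0, 0] == pytest.approx((255 / 511) / 766)

    def test_palette_ordering(self):
        """Nuclei stain scores above cytoplasm, making role assignment valid."""
        def br(color):
            img = np.array(color, dtype=np.uint8).reshape(1, 1, 3)
            return blue_ratio_image(img)[0, 0]

        assert br(DEFAULT_STAIN_COLORS["nuclei"]) > br(DEFAULT_STAIN_COLORS["cytoplasm"])
        assert br(DEFAULT_STAIN_COLORS["cytoplasm"]) > 0

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            blue_ratio_image(np.zeros((4, 4)))


class TestEpithelium:
    def test_dice_against_ground_truth(self, dysplasia_crop):
        rgb, gt = dysplasia_crop
        mask = segment_epithelium(rgb)
        assert _dice(mask, gt.epithelium_mask) >= 0.90

    def test_all_white_image_is_empty_with_warning(self):
        img = np.full((40, 40, 3), 250, dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = segment_epithelium(img)
        assert not mask.any()

    def test_output_has_no_holes(self, normal_crop):
        rgb, _ = normal_crop
        mask = segment_epithelium(rgb)
        assert np.array_equal(mask, ndi.binary_fill_holes(mask))


class TestPartition:
    def test_exact_palette_recovered(self):
        """Separable three-color epithelium: each mask is exactly its color."""
        img = np.empty((30, 30, 3), dtype=np.uint8)
        img[...] = DEFAULT_STAIN_COLORS["cytoplasm"]
        img[5:12, 5:12] = DEFAULT_STAIN_COLORS["nuclei"]
        img[18:24, 18:24] = DEFAULT_STAIN_COLORS["background"]
        epi = np.ones((30, 30), dtype=bool)
        nuc, cyt, bg = partition_epithelium(img, epi)
        assert np.array_equal(
            nuc, (img == DEFAULT_STAIN_COLORS["nuclei"]).all(axis=-1)
        )
        assert np.array_equal(
            bg, (img == DEFAULT_STAIN_COLORS["background"]).all(axis=-1)
        )
        assert np.array_equal(
            cyt, (img == DEFAULT_STAIN_COLORS["cytoplasm"]).all(axis=-1)
        )

    def test_empty_epithelium_rejected(self, normal_crop):
        rgb, _ = normal_crop
        with pytest.raises(ValueError):
            partition_epithelium(rgb, np.zeros(rgb.shape[:2], dtype=bool))

    def test_nuclei_recall_on_synthetic_crop(self, normal_crop):
        rgb, gt = normal_crop
        nuc, _, _ = partition_epithelium(rgb, gt.epithelium_mask)
        truth = gt.nuclei_labels > 0
        recall = (nuc & truth).sum() / truth.sum()
        assert recall >= 0.9

    def test_degenerate_two_color_input(self):
        img = np.empty((20, 20, 3), dtype=np.uint8)
        img[...] = DEFAULT_STAIN_COLORS["cytoplasm"]
        img[5:10, 5:10] = DEFAULT_STAIN_COLORS["nuclei"]
        nuc, cyt, bg = partition_epithelium(img, np.ones((20, 20), dtype=bool))
        assert nuc.sum() == 25
        assert not (nuc & cyt).any()


class TestRefine:
    def test_thin_component_under_50px_removed(self):
        mask = np.zeros((30, 80), dtype=bool)
        mask[15, 10:59] = True  # 49 px, destroyed by the r=4 opening
        assert not refine_nuclei_mask(mask).any()

    def test_hole_filled(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = draw_disk((20, 20), 10)
        mask[rr, cc] = True
        mask[19:21, 19:21] = False
        out = refine_nuclei_mask(mask)
        assert out[19:21, 19:21].all()

    def test_nearby_disks_merged_by_dilation(self):
        """Disks r=6 with a 3 px gap: bridged by the r=2 dilation and the
        bridge survives the r=4 opening."""
        mask = np.zeros((40, 60), dtype=bool)
        for c in (20, 35):
            rr, cc = draw_disk((20, c), 6)
            mask[rr, cc] = True
        assert measure.label(mask).max() == 2
        out = refine_nuclei_mask(mask)
        assert measure.label(out).max() == 1

    def test_survivors_at_least_50px(self, normal_crop):
        rgb, gt = normal_crop
        nuc, _, _ = partition_epithelium(rgb, gt.epithelium_mask)
        out = refine_nuclei_mask(nuc)
        areas = [r.area for r in measure.regionprops(measure.label(out))]
        assert all(a >= 50 for a in areas)


class TestSplitLarge:
    def test_convex_component_unchanged(self):
        mask = np.zeros((50, 50), dtype=bool)
        rr, cc = ellipse(25, 25, 16, 12)  # solidity ~1, area > 500
        mask[rr, cc] = True
        img = np.full((50, 50, 3), (64, 48, 128), dtype=np.uint8)
        out = split_large_clusters(mask, img)
        assert np.array_equal(out, mask)

    def test_dumbbell_split_into_two(self):
        mask, img = bridged_dumbbell(12, 7, 6, 2)
        region = measure.regionprops(measure.label(mask))[0]
        assert region.area > 500 and region.solidity < 0.9
        out = split_large_clusters(mask, img)
        assert measure.label(out).max() == 2

    def test_red_blob_removed_as_false_detection(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = ellipse(20, 20, 10, 8)
        mask[rr, cc] = True
        img = np.full((40, 40, 3), (200, 40, 100), dtype=np.uint8)  # R/B = 2.0
        assert not split_large_clusters(mask, img).any()

    def test_idempotent_on_own_output(self):
        mask, img = bridged_dumbbell(12, 7, 6, 2)
        once = split_large_clusters(mask, img)
        twice = split_large_clusters(once, img)
        assert np.array_equal(once, twice)


class TestSplitSmall:
    def test_small_convex_nucleus_unchanged(self):
        mask = np.zeros((30, 30), dtype=bool)
        rr, cc = ellipse(15, 15, 7, 6)  # ~130 px, below the 150 px trigger
        mask[rr, cc] = True
        img = np.full((30, 30, 3), (64, 48, 128), dtype=np.uint8)
        out = split_small_clusters(mask, img)
        assert measure.label(out).max() == 1
        assert np.array_equal(out, mask)

    def test_touching_pair_separated(self):
        mask, img = bridged_dumbbell(9, 6, 8, 2)
        region = measure.regionprops(measure.label(mask))[0]
        assert region.area > 150 and region.solidity < 0.9
        out = split_small_clusters(mask, img)
        assert measure.label(out).max() == 2

    def test_fragment_under_50px_discarded(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:15, 10:18] = True  # 40 px
        img = np.full((30, 30, 3), (64, 48, 128), dtype=np.uint8)
        assert not split_small_clusters(mask, img).any()


class TestFinalize:
    def test_blue_kept_pink_removed(self):
        mask = np.zeros((40, 80), dtype=bool)
        img = np.zeros((40, 80, 3), dtype=np.uint8)
        rr, cc = ellipse(20, 20, 8, 7)
        mask[rr, cc] = True
        img[rr, cc] = (60, 45, 130)  # R/B = 0.46
        rr, cc = ellipse(20, 55, 8, 7)
        mask[rr, cc] = True
        img[rr, cc] = (230, 150, 180)  # R/B = 1.28
        labels, records = finalize_nuclei(mask, img)
        assert len(records) == 1
        assert records[0].mean_rb_ratio <= 1.0
        assert records[0].minor_axis <= records[0].major_axis

    def test_empty_mask_is_valid(self):
        labels, records = finalize_nuclei(
            np.zeros((10, 10), dtype=bool), np.zeros((10, 10, 3), dtype=np.uint8)
        )
        assert labels.max() == 0 and records == []


class TestPipeline:
    def test_count_recovery_on_sparse_crops(self, sparse_spec):
        import dataclasses

        for seed in range(5):
            spec = dataclasses.replace(sparse_spec, seed=seed)
            rgb, gt = generate_he_image(spec)
            _, records = segment_tissue(rgb)
            assert abs(len(records) - gt.n_nuclei) / gt.n_nuclei <= 0.10

    def test_final_nuclei_invariants(self, dysplasia_crop):
        rgb, _ = dysplasia_crop
        masks, records = segment_tissue(rgb)
        nuclei = masks.nuclei_labels > 0
        # confined to epithelium, >= 25 px, mean R/B <= 1
        assert not (nuclei & ~masks.epithelium).any()
        for rec in records:
            assert rec.area >= 25
            assert rec.mean_rb_ratio <= 1.0
        # compartments partition the epithelium without overlap
        assert not (masks.cytoplasm & nuclei).any()
        assert not (masks.background & nuclei).any()
        assert not (masks.cytoplasm & masks.background).any()
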