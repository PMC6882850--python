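"""Feature extractors: frozen oracle values, proportion invariants, and the
block arithmetic that fixes the 712-dimensional bank."""

from __future__ import annotations

import numpy as np
import pytest

from histospec.config import TextureParams
from histospec.features import (
    TOTAL_FEATURE_COUNT,
    assemble_features,
    color_features,
    fractal_dimension,
    gabor_features,
    glcm_features,
    lbp_features,
    luminance,
    morphometric_features,
    msfta_features,
    texture_features,
    topology_features,
)
from histospec.features.fractal import msfta_binary_images
from histospec.features.texture import cooccurrence_matrix, gabor_filter_bank
from histospec.segmentation import TissueMasks, segment_tissue
from tests.conftest import sierpinski_carpet


def _by_name(block):
    return dict(zip(block.names, block.values))


def _valid_by_name(block):
    return dict(zip(block.names, block.valid))


class TestColor:
    def _random_image(self, seed=0, shape=(40, 40)):
        rng = np.random.default_rng(seed)
        return rng.integers(0, 180, size=shape + (3,)).astype(np.uint8)

    def test_histograms_are_proportions(self):
        img = self._random_image()
        block = color_features(img, np.ones(img.shape[:2], dtype=bool))
        vals = _by_name(block)
        for ch in ("r", "g", "b"):
            s = sum(v for n, v in vals.items() if n.startswith(f"color.trgb_{ch}."))
            assert s == pytest.approx(1.0)
        s = sum(v for n, v in vals.items() if n.startswith("color.rbdiff.bin"))
        assert s == pytest.approx(1.0)

    def test_intensity_scale_invariance(self):
        """Standardization cancels a common gain on the float path."""
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 90, size=(30, 30, 3))  # luminance well below 180
        mask = np.ones((30, 30), dtype=bool)
        a = color_features(img, mask)
        b = color_features(img * 1.5, mask)
        trgb = [i for i, n in enumerate(a.names) if n.startswith("color.trgb")]
        assert np.allclose(a.values[trgb], b.values[trgb])

    def test_constant_region_degenerates_gracefully(self):
        img = np.full((20, 20, 3), (120, 60, 90), dtype=np.uint8)
        block = color_features(img, np.ones((20, 20), dtype=bool))
        vals, ok = _by_name(block), _valid_by_name(block)
        # all mass in the central bin of each standardized channel
        for ch in ("r", "g", "b"):
            assert vals[f"color.trgb_{ch}.bin08"] == 1.0
            assert not ok[f"color.trgb_{ch}.bin08"]
        for stat in ("std", "skewness", "kurtosis"):
            assert vals[f"color.rbdiff.{stat}"] == 0.0
            assert not ok[f"color.rbdiff.{stat}"]

    def test_white_pixels_dropped_by_luminance_cutoff(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        img[:5] = (120, 60, 90)
        full = color_features(img, np.ones((10, 10), dtype=bool))
        half = color_features(img, np.vstack([np.ones((5, 10)), np.zeros((5, 10))]).astype(bool))
        assert np.allclose(full.values, half.values)

    def test_empty_after_white_removal_flagged(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        block = color_features(img, np.ones((10, 10), dtype=bool))
        assert not block.valid.any()
        assert (block.values == 0).all()


class TestGLCM:
    def test_constant_region(self):
        img = np.full((20, 20), 7.0)
        block = glcm_features(img, np.ones((20, 20), dtype=bool))
        vals, ok = _by_name(block), _valid_by_name(block)
        assert vals["glcm.asm"] == pytest.approx(1.0)
        assert vals["glcm.contrast"] == 0.0
        assert not ok["glcm.correlation"]

    def test_averaged_matrix_is_probability(self, normal_crop):
        from histospec.features.texture import averaged_glcm

        rgb, gt = normal_crop
        p = averaged_glcm(luminance(rgb), gt.epithelium_mask)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    def test_checkerboard_contrast_by_hand_count(self):
        """4x4 two-level checkerboard, horizontal distance 1: every pair
        differs by one level, so contrast of the normalized matrix is 1."""
        board = np.indices((4, 4)).sum(axis=0) % 2
        m = cooccurrence_matrix(board, np.ones((4, 4), dtype=bool), (0, 1), 2)
        p = m / m.sum()
        i, j = np.indices(p.shape)
        assert (((i - j) ** 2) * p).sum() == pytest.approx(1.0)
        assert p[0, 0] == 0 and p[1, 1] == 0  # all mass off-diagonal

    def test_masked_pairs_dropped(self):
        img = np.array([[0.0, 63.0], [0.0, 63.0]])
        mask = np.array([[True, False], [True, True]])
        m = cooccurrence_matrix(
            np.where(img > 0, 1, 0), mask, (0, 1), 2
        )
        # only the bottom row pair is valid
        assert m.sum() == 2  # symmetric count of a single pair


class TestGabor:
    def test_filter_bank_has_28_kernels(self):
        assert len(gabor_filter_bank(320)) == 28

    def test_constant_image_zero_entropy(self):
        img = np.full((40, 60), 50.0)
        block = gabor_features(img, np.ones((40, 60), dtype=bool))
        ent = [v for n, v in zip(block.names, block.values) if n.endswith("entropy")]
        assert np.allclose(ent, 0.0)

    def test_grating_maximizes_matched_filter(self):
        """A horizontal-frequency grating at the k=2 radial frequency puts
        the most energy in the orientation/frequency-matched filter."""
        W, H = 384, 64
        u0 = 8 * np.sqrt(2.0)
        x = np.arange(W)[None, :]
        img = 128 + 100 * np.cos(2 * np.pi * u0 * x / W) * np.ones((H, 1))
        block = gabor_features(img, np.ones((H, W), dtype=bool))
        energies = {
            n: v for n, v in zip(block.names, block.values) if n.endswith("energy")
        }
        assert max(energies, key=energies.get) == "gabor.o0_f2.energy"


class TestLBP:
    def test_histogram_is_proportion(self, normal_crop):
        rgb, gt = normal_crop
        block = lbp_features(luminance(rgb), gt.epithelium_mask)
        assert block.values.sum() == pytest.approx(1.0)

    def test_constant_image_single_bin(self):
        img = np.full((20, 20), 99.0)
        block = lbp_features(img, np.ones((20, 20), dtype=bool))
        assert np.sort(block.values)[-1] == pytest.approx(1.0)
        assert (block.values > 0).sum() == 1

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 255, size=(41, 41)).astype(float)
        mask = np.ones((41, 41), dtype=bool)
        a = lbp_features(img, mask)
        b = lbp_features(np.rot90(img).copy(), mask)
        assert np.allclose(a.values, b.values)


class TestMSFTA:
    def _textured(self, seed=0, shape=(60, 60)):
        rng = np.random.default_rng(seed)
        return rng.choice([40.0, 90.0, 150.0, 210.0], size=shape), np.ones(shape, bool)

    def test_eight_binary_images(self):
        gray, mask = self._textured()
        assert len(msfta_binary_images(gray, mask)) == 8

    def test_feature_count_is_64(self):
        gray, mask = self._textured()
        assert len(msfta_features(gray, mask)) == 64

    def test_binary_images_partition_upper_and_band_sets(self):
        gray, mask = self._textured(1)
        imgs = msfta_binary_images(gray, mask)
        upper, bands = imgs[:4], imgs[4:]
        # each band set lies inside its upper set and excludes the next one
        for i in range(3):
            assert (bands[i] <= upper[i]).all()
            assert not (bands[i] & upper[i + 1]).any()

    def test_constant_region_invalid(self):
        block = msfta_features(np.full((20, 20), 5.0), np.ones((20, 20), bool))
        assert not block.valid.any()

    def test_empty_binary_images_flagged_not_nan(self):
        # two distinct levels < 5 classes: thresholds collapse
        gray = np.where(np.arange(400).reshape(20, 20) % 2 == 0, 10.0, 200.0)
        block = msfta_features(gray, np.ones((20, 20), bool))
        assert np.isfinite(block.values).all()


class TestFractalDimension:
    def test_straight_line_has_dimension_one(self):
        img = np.zeros((256, 256), dtype=bool)
        img[128, :] = True
        fd, ok = fractal_dimension(img)
        assert ok and abs(fd - 1.0) <= 0.1

    def test_filled_square_has_dimension_two(self):
        fd, ok = fractal_dimension(np.ones((256, 256), dtype=bool))
        assert ok and abs(fd - 2.0) <= 0.1

    def test_sierpinski_carpet_closed_form(self):
        fd, ok = fractal_dimension(sierpinski_carpet(4))
        assert ok and abs(fd - np.log(8) / np.log(3)) <= 0.1

    def test_empty_image_flagged(self):
        fd, ok = fractal_dimension(np.zeros((16, 16), dtype=bool))
        assert fd == 0.0 and not ok


class TestMorphometry:
    def test_vector_length_is_44(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1
        block = morphometric_features(labels, np.ones((40, 40), bool))
        assert len(block) == 44

    def test_circle_closed_forms(self):
        from skimage.draw import disk as draw_disk

        labels = np.zeros((64, 64), dtype=np.int32)
        rr, cc = draw_disk((32, 32), 15)
        labels[rr, cc] = 1
        vals = _by_name(morphometric_features(labels, np.ones((64, 64), bool)))
        assert abs(vals["morph.eccentricity.mean"]) <= 0.1
        assert abs(vals["morph.compactness.mean"] - 1.0) <= 0.1

    def test_neighborhood_radius_two_nuclei(self):
        labels = np.zeros((40, 80), dtype=np.int32)
        labels[18:23, 18:23] = 1
        labels[18:23, 48:53] = 2  # centroids 30 px apart
        vals = _by_name(morphometric_features(labels, np.ones((40, 80), bool)))
        assert vals["morph.neighborhood_radius.mean"] == pytest.approx(15.0)

    def test_single_nucleus_spread_flagged(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[10:20, 10:20] = 1
        block = morphometric_features(labels, np.ones((30, 30), bool))
        ok = _valid_by_name(block)
        assert not ok["morph.area.std"]
        assert not ok["morph.neighborhood_radius.mean"]
        assert ok["morph.area.mean"]

    def test_zero_cytoplasm_flags_nc_ratio(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:15, 5:15] = 1
        block = morphometric_features(labels, np.zeros((30, 30), bool))
        assert not _valid_by_name(block)["morph.nc_ratio"]

    def test_no_nuclei_all_invalid(self):
        block = morphometric_features(np.zeros((10, 10), np.int32), np.ones((10, 10), bool))
        assert not block.valid.any() and (block.values == 0).all()


class TestTopology:
    def test_345_right_triangle(self):
        pts = np.array([[0, 0], [3, 0], [3, 4]], dtype=float)
        vals = _by_name(topology_features(pts))
        assert vals["topo.area.mean"] == pytest.approx(6.0)
        assert vals["topo.area.max"] == pytest.approx(6.0)
        assert vals["topo.area.min"] == pytest.approx(6.0)
        assert vals["topo.perimeter.mean"] == pytest.approx(12.0)
        assert vals["topo.area.disorder"] == 0.0

    def test_unit_square_two_equal_triangles(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        vals = _by_name(topology_features(pts))
        assert vals["topo.area.mean"] == pytest.approx(0.5)
        assert vals["topo.area.disorder"] == pytest.approx(0.0)

    def test_clustered_points_more_disordered_than_grid(self):
        """Perimeter disorder separates clustered from jittered-grid layouts."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gx, gy = np.meshgrid(np.arange(6) * 20.0, np.arange(6) * 20.0)
            grid = np.column_stack([gx.ravel(), gy.ravel()])
            grid += rng.uniform(-2, 2, grid.shape)
            centers = rng.uniform(0, 100, (4, 2))
            clustered = np.concatenate(
                [c + rng.normal(0, 3, (9, 2)) for c in centers]
            )
            d_grid = _by_name(topology_features(grid))["topo.perimeter.disorder"]
            d_clu = _by_name(topology_features(clustered))["topo.perimeter.disorder"]
            wins += d_clu > d_grid
        assert wins >= 9

    def test_degenerate_inputs_flagged(self):
        assert not topology_features(np.array([[0, 0], [1, 1]])).valid.any()
        collinear = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        assert not topology_features(collinear).valid.any()


class TestAssembly:
    def test_structure_and_counts(self, dysplasia_crop):
        rgb, _ = dysplasia_crop
        masks, _ = segment_tissue(rgb)
        fv = assemble_features(rgb, masks)
        assert len(fv) == TOTAL_FEATURE_COUNT == 712
        comp_counts = {}
        for name in fv.names:
            comp_counts[name.split(".")[0]] = comp_counts.get(name.split(".")[0], 0) + 1
        assert comp_counts == {"epithelium": 220, "cytoplasm": 220, "nuclei": 272}
        assert len(set(fv.names)) == 712
        assert np.isfinite(fv.values).all()

    def test_texture_block_is_149(self, normal_crop):
        rgb, gt = normal_crop
        block = texture_features(luminance(rgb), gt.epithelium_mask)
        assert len(block) == 149 == 19 + 56 + 10 + 64

    def test_empty_nuclei_still_full_length(self, normal_crop):
        rgb, gt = normal_crop
        masks = TissueMasks(
            epithelium=gt.epithelium_mask,
            nuclei_labels=np.zeros(rgb.shape[:2], dtype=np.int32),
            cytoplasm=gt.epithelium_mask.copy(),
            background=np.zeros(rgb.shape[:2], dtype=bool),
        )
        fv = assemble_features(rgb, masks)
        assert len(fv) == 712
        morph = [i for i, n in enumerate(fv.names) if ".morph." in n or ".topo." in n]
        assert not fv.valid[morph].any()
        assert (fv.values[morph] == 0).all()

    def test_name_order_stable_across_runs(self, normal_crop):
        rgb, _ = normal_crop
        masks, _ = segment_tissue(rgb)
        a = assemble_features(rgb, masks)
        b = assemble_features(rgb, masks)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_irregularity_raises_epithelium_fractal_dimension(self):
        """The outline-irregularity knob moves the edge fractal dimension the
        way graded atypia does, across 10 seeds."""
        from histospec.synthetic import TissueSpec, generate_he_image

        wins = 0
        for seed in range(10):
            fds = []
            for irr in (0.02, 0.30):
                spec = TissueSpec(
                    n_nuclei=25, boundary_irregularity=irr, crowding=0.8, seed=seed
                )
                rgb, gt = generate_he_image(spec)
                block = msfta_features(luminance(rgb), gt.epithelium_mask)
                vals = dict(zip(block.names, block.values))
                fds.append(vals["msfta.b0.edge.fractal_dimension"])
            wins += fds[1] > fds[0]
        assert wins >= 9
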