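import math

import numpy as np
import pytest

from lungseg.image_model import GrayImage, LabelMask
from lungseg.resize import (LowResImage, LowResMask, SuperpixelResizer,
                            baseline_resize, classify_boundary,
                            downsample_image, downsample_mask,
                            grid_dims_from_rate, roundtrip, upsample_image,
                            upsample_labels)
from lungseg.useq import extract_superpixels, init_grid
from tests.conftest import stripe_image


class TestClassifyBoundary:
    def test_corner_cells_keep_one_homogeneous_pixel(self):
        # 4x4 image, 2x2 cells: only the image-corner pixel of each cell has
        # all its 4-neighbors inside the same cell
        store = classify_boundary(init_grid(4, 4, 2, 2))
        for i in range(4):
            assert len(store.boundary_of(i)) == 3
            assert len(store.homogeneous_of(i)) == 1

    def test_4x4_cells_split_seven_nine(self):
        store = classify_boundary(init_grid(8, 8, 2, 2))
        for i in range(4):
            assert len(store.boundary_of(i)) == 7
            assert len(store.homogeneous_of(i)) == 9

    def test_single_superpixel_has_no_boundary(self):
        store = classify_boundary(init_grid(5, 5, 1, 1))
        assert not store.boundary_mask.any()

    def test_partition_matches_brute_force(self, rng):
        img = rng.integers(0, 256, size=(12, 12))
        spmap, _ = extract_superpixels(img, 3, 3)
        store = classify_boundary(spmap)
        lab = spmap.labels
        for r in range(12):
            for c in range(12):
                nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                expect = any(0 <= rr < 12 and 0 <= cc < 12
                             and lab[rr, cc] != lab[r, c] for rr, cc in nbrs)
                assert store.boundary_mask[r, c] == expect


class TestDownsampleImage:
    def test_constant_superpixels_pass_through(self):
        img = np.kron(np.array([[10, 20], [30, 40]]), np.ones((4, 4), dtype=int))
        spmap = init_grid(8, 8, 2, 2)
        low = downsample_image(img, spmap, classify_boundary(spmap))
        np.testing.assert_array_equal(low.values, [[10, 20], [30, 40]])

    def test_mean_of_homogeneous_set_rounded(self):
        # 8x8 image, 2x2 grid: homogeneous set of cell 0 is its top-left 3x3
        img = np.zeros((8, 8), dtype=np.int64)
        img[:3, :3] = [[10, 10, 12], [12, 10, 10], [12, 12, 11]]
        spmap = init_grid(8, 8, 2, 2)
        low = downsample_image(img, spmap, classify_boundary(spmap))
        assert low.values[0, 0] == 11  # mean 11.0 of {10x4, 12x4, 11}

    def test_all_boundary_cell_falls_back_to_full_mean(self):
        # center cell of a 3x3 grid of 2x2 cells has no homogeneous pixels
        img = np.zeros((6, 6), dtype=np.int64)
        img[2:4, 2:4] = [[10, 20], [30, 40]]
        spmap = init_grid(6, 6, 3, 3)
        store = classify_boundary(spmap)
        assert len(store.homogeneous_of(4)) == 0
        low = downsample_image(img, spmap, store)
        assert low.values[1, 1] == 25

    def test_shape_is_grid(self, phantom_pair):
        image, _ = phantom_pair
        spmap, _ = extract_superpixels(image, 64, 32)
        low = downsample_image(image, spmap, classify_boundary(spmap))
        assert low.values.shape == (32, 64)


class TestDownsampleMask:
    def test_pure_and_majority_votes(self):
        mask = np.zeros((4, 8), dtype=np.int64)
        mask[:, :4] = 1          # left cell 100% lung
        mask[:3, 4:7] = 1        # right cell: 9 lung / 7 background
        spmap = init_grid(8, 4, 2, 1)
        low = downsample_mask(mask, spmap)
        np.testing.assert_array_equal(low.labels, [[1, 1]])

    def test_exact_tie_goes_to_background(self):
        mask = np.zeros((4, 4), dtype=np.int64)
        mask[:2, :] = 1  # 8 lung / 8 background in the single superpixel
        low = downsample_mask(mask, init_grid(4, 4, 1, 1))
        assert low.labels[0, 0] == 0

    def test_multiclass_plurality_lower_label_ties(self):
        mask = np.array([[0, 0, 1, 1], [2, 2, 1, 0]])
        low = downsample_mask(LabelMask(mask, n_classes=3),
                              init_grid(4, 2, 1, 1))
        assert low.labels[0, 0] == 0  # 0 and 1 tie at 3 votes; lower wins


class TestUpsample:
    def test_mask_roundtrip_identity_on_aligned_masks(self, rng):
        spmap, _ = extract_superpixels(rng.integers(0, 256, (16, 16)), 4, 4)
        store = classify_boundary(spmap)
        per_sp = rng.integers(0, 2, size=16)
        mask = per_sp[spmap.labels]
        low = downsample_mask(mask, spmap)
        back = upsample_labels(low, spmap, store)
        np.testing.assert_array_equal(back.labels, mask)

    def test_all_background_lowres_gives_zero_mask(self):
        spmap = init_grid(8, 8, 2, 2)
        low = LowResMask(np.zeros((2, 2), dtype=np.int64), spmap)
        assert not upsample_labels(low, spmap, classify_boundary(spmap)).labels.any()

    def test_checkerboard_block_expansion(self):
        spmap = init_grid(8, 8, 2, 2)
        low = LowResMask(np.array([[0, 1], [1, 0]]), spmap)
        out = upsample_labels(low, spmap, classify_boundary(spmap))
        np.testing.assert_array_equal(
            out.labels, np.kron([[0, 1], [1, 0]], np.ones((4, 4), dtype=int)))

    def test_image_roundtrip_exact_on_cell_aligned_regions(self, rng):
        img = np.kron(rng.integers(0, 256, (4, 4)), np.ones((4, 4), dtype=int))
        spmap, _ = extract_superpixels(img, 4, 4)
        store = classify_boundary(spmap)
        low = downsample_image(img, spmap, store)
        back = upsample_image(low, spmap, store)
        np.testing.assert_array_equal(back.values, img)

    def test_upsample_requires_captured_store(self):
        spmap = init_grid(8, 8, 2, 2)
        store = classify_boundary(spmap)
        low = LowResImage(np.zeros((2, 2), dtype=np.int64), spmap)
        with pytest.raises(ValueError, match="captured"):
            upsample_image(low, spmap, store)

    def test_step_edge_exact_while_bicubic_lossy(self):
        img = np.full((64, 64), 40, dtype=np.int64)
        img[:, 33:] = 200  # edge 1 px off the rate-0.25 grid lines
        rec_u, p_u = roundtrip(GrayImage(img), 0.25, "useq")
        rec_b, p_b = roundtrip(GrayImage(img), 0.25, "bicubic")
        assert math.isinf(p_u)
        np.testing.assert_array_equal(rec_u.values, img)
        assert (rec_b.values != img).any() and math.isfinite(p_b)


class TestBaselineResize:
    def test_nearest_integer_factor_is_block_replication(self):
        img = GrayImage(np.array([[1, 2], [3, 4]]))
        out = baseline_resize(img, 4, 4, "nearest")
        np.testing.assert_array_equal(
            out.values, np.kron([[1, 2], [3, 4]], np.ones((2, 2), dtype=int)))

    def test_bilinear_midpoint_rounds_half_up(self):
        out = baseline_resize(GrayImage(np.array([[0, 255]])), 3, 1, "bilinear")
        np.testing.assert_array_equal(out.values, [[0, 128, 255]])

    @pytest.mark.parametrize("method", ["nearest", "bilinear", "bicubic"])
    def test_same_size_is_identity(self, method, rng):
        img = GrayImage(rng.integers(0, 256, (9, 7)))
        out = baseline_resize(img, 7, 9, method)
        np.testing.assert_array_equal(out.values, img.values)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            baseline_resize(GrayImage(np.zeros((4, 4), dtype=int)), 2, 2, "lanczos")


class TestRoundtrip:
    def test_rate_one_is_identity_with_inf_psnr(self, rng):
        img = GrayImage(rng.integers(0, 256, (16, 16)))
        rec, p = roundtrip(img, 1.0, "useq")
        np.testing.assert_array_equal(rec.values, img.values)
        assert math.isinf(p)

    def test_degenerate_rate_rejected(self):
        with pytest.raises(ValueError):
            grid_dims_from_rate(16, 16, 0.01)

    def test_useq_beats_nearest_on_aligned_phantom(self, rng):
        img = GrayImage(stripe_image(rng))
        _, p_u = roundtrip(img, 0.25, "useq")
        _, p_n = roundtrip(img, 0.25, "nearest")
        assert p_u >= p_n

    def test_monotone_degradation_with_rate(self, phantom_pair):
        """PSNR of the useq round trip does not increase as the rate drops."""
        image, _ = phantom_pair
        psnrs = [roundtrip(image, r, "useq")[1] for r in (0.5, 0.25, 0.125)]
        assert psnrs[0] >= psnrs[1] >= psnrs[2]


class TestSuperpixelResizerEstimator:
    def test_transform_inverse_transform_cycle(self, phantom_pair):
        image, mask = phantom_pair
        est = SuperpixelResizer(rate=0.25).fit(image)
        low = est.transform(image)
        assert low.shape == (64, 64)
        recon = est.inverse_transform(low)
        assert recon.shape == image.shape
        low_mask = est.transform_mask(mask)
        full = est.inverse_transform_labels(low_mask)
        assert full.shape == image.shape

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = SuperpixelResizer(rate=0.5, n_bins=8)
        assert clone(est).get_params()["n_bins"] == 8
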