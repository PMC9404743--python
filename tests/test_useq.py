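import numpy as np
import pytest

from lungseg.image_model import GrayImage
from lungseg.metrics import boundary_pixels
from lungseg.resize import classify_boundary
from lungseg.useq import (UseqSuperpixels, adjacency, extract_superpixels,
                          init_grid, load_superpixel_map, map_reassign,
                          quantize_colors, save_superpixel_map,
                          _grid_adjacency, default_lambdas)


class TestInitGrid:
    def test_exact_division(self):
        g = init_grid(2048, 2048, 256, 256)
        assert g.cell_w == 8 and g.cell_h == 8

    def test_four_cell_partition(self):
        g = init_grid(4, 4, 2, 2)
        np.testing.assert_array_equal(
            g.labels, [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]])

    def test_remainder_absorbed_by_edge_cells(self):
        g = init_grid(5, 5, 2, 2)
        assert g.cell_w == 3
        np.testing.assert_array_equal(np.bincount(g.labels[0] % 2), [3, 2])

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            init_grid(4, 4, 5, 2)

    def test_partition_invariant(self, rng):
        g = init_grid(37, 23, 7, 5)
        counts = g.pixel_counts()
        assert counts.sum() == 37 * 23
        assert len(counts) == 35


class TestAdjacency:
    def test_two_by_two_grid(self):
        adj = adjacency(init_grid(4, 4, 2, 2))
        assert adj.is_adjacent(0, 1) and adj.is_adjacent(0, 2)
        assert adj.is_adjacent(1, 3) and adj.is_adjacent(2, 3)
        assert not adj.is_adjacent(0, 3) and not adj.is_adjacent(1, 2)

    def test_single_superpixel_has_no_neighbors(self):
        adj = adjacency(init_grid(3, 3, 1, 1))
        assert adj.pairs.shape == (0, 2)

    def test_center_cell_of_3x3_grid_vs_pixel_scan(self):
        g = init_grid(9, 9, 3, 3)
        adj = adjacency(g)
        # brute-force: scan all 4-neighbor pixel pairs
        lab = g.labels
        found = set()
        for r in range(9):
            for c in range(9):
                for dr, dc in ((0, 1), (1, 0)):
                    if r + dr < 9 and c + dc < 9 and lab[r, c] != lab[r + dr, c + dc]:
                        found.add(tuple(sorted((lab[r, c], lab[r + dr, c + dc]))))
        assert set(map(tuple, adj.pairs)) == found
        assert len(adj.neighbors(4)) == 4  # center cell

    def test_symmetric_and_irreflexive(self):
        adj = adjacency(init_grid(8, 8, 4, 2))
        for i, j in adj.pairs:
            assert i != j and adj.is_adjacent(j, i)


class TestQuantizeColors:
    def test_constant_superpixel_dominant_is_bin_midpoint(self):
        g = init_grid(8, 8, 2, 2)
        stats = quantize_colors(np.full((8, 8), 100), g)
        # 100 falls in bin [96, 112) whose midpoint is 104
        assert np.allclose(stats.dominant, 104.0)

    def test_mode_bin_wins(self):
        g = init_grid(2, 2, 1, 1)
        stats = quantize_colors(np.array([[0, 0], [0, 255]]), g)
        assert stats.dominant[0] == 8.0  # midpoint of the bin holding 0

    def test_whole_image_constant_gives_equal_dominants(self, rng):
        v = int(rng.integers(0, 256))
        stats = quantize_colors(np.full((12, 12), v), init_grid(12, 12, 3, 3))
        assert len(set(stats.dominant.tolist())) == 1

    def test_centroids_and_counts(self):
        g = init_grid(4, 4, 2, 2)
        stats = quantize_colors(np.zeros((4, 4)), g)
        assert stats.counts.sum() == 16
        np.testing.assert_allclose(stats.centroids[0], [0.5, 0.5])


class TestMapReassign:
    def _setup(self, img, gw, gh):
        H, W = img.shape
        grid = init_grid(W, H, gw, gh)
        stats = quantize_colors(img, grid)
        return grid, stats, _grid_adjacency(gw, gh)

    def test_constant_image_keeps_grid(self):
        img = np.full((8, 8), 77)
        grid, stats, adj = self._setup(img, 2, 2)
        ls, lc = default_lambdas(grid)
        out = map_reassign(img, grid, stats, adj, ls, lc)
        np.testing.assert_array_equal(out.labels, grid.labels)

    def test_pure_spatial_term_reproduces_grid(self, rng):
        img = rng.integers(0, 256, size=(12, 16))
        grid, stats, adj = self._setup(img, 4, 3)
        out = map_reassign(img, grid, stats, adj, 1.0, 0.0)
        np.testing.assert_array_equal(out.labels, grid.labels)

    def test_color_term_moves_offset_edge_pixel(self):
        # step edge 1 px into cell 0; with lambda_s = 0 the stray column
        # joins the cell whose dominant color matches
        img = np.zeros((4, 8), dtype=np.int64)
        img[:, 3:] = 200  # cells are 4 wide; col 3 is bright inside cell 0
        grid, stats, adj = self._setup(img, 2, 1)
        out = map_reassign(img, grid, stats, adj, 0.0, 1.0)
        assert (out.labels[:, 3] == 1).all()
        assert (out.labels[:, :3] == 0).all()

    def test_superpixel_count_unchanged(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        grid, stats, adj = self._setup(img, 4, 4)
        ls, lc = default_lambdas(grid)
        out = map_reassign(img, grid, stats, adj, ls, lc)
        assert out.n_superpixels == 16
        assert out.labels.max() < 16 and out.labels.min() >= 0


class TestExtractSuperpixels:
    def test_constant_image_final_equals_grid(self):
        spmap, _ = extract_superpixels(np.full((16, 16), 42), 4, 4)
        np.testing.assert_array_equal(spmap.labels, init_grid(16, 16, 4, 4).labels)

    def test_partition_and_count(self, rng):
        img = rng.integers(0, 256, size=(32, 24))
        spmap, stats = extract_superpixels(img, 6, 8)
        assert spmap.n_superpixels == 48
        assert spmap.pixel_counts().sum() == 32 * 24
        assert stats.counts.sum() == 32 * 24

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, size=(32, 32))
        a, _ = extract_superpixels(img, 8, 8)
        b, _ = extract_superpixels(img, 8, 8)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_boundary_recall_on_phantom_edge(self, phantom_pair):
        """Superpixel boundaries adhere to the lung edges: >= 95% of true
        edge pixels lie within 1 px of a superpixel boundary."""
        from scipy.spatial import cKDTree

        image, mask = phantom_pair
        spmap, _ = extract_superpixels(image, 64, 64)
        store = classify_boundary(spmap)
        edge = boundary_pixels(mask.labels).astype(float)
        spb = np.argwhere(store.boundary_mask).astype(float)
        dists = cKDTree(spb).query(edge)[0]
        assert (dists <= 1.0).mean() >= 0.95

    def test_reassignment_does_not_worsen_edge_distance(self):
        """Mean distance from a step edge to the superpixel boundaries is no
        larger after MAP reassignment than on the initial grid."""
        from scipy.spatial import cKDTree

        img = np.full((32, 32), 40, dtype=np.int64)
        img[:, 18:] = 200  # edge offset 2 px into a cell (cells 4 wide)
        edge = np.array([[r, 17.5] for r in range(32)])

        def mean_dist(labels):
            from lungseg.useq import SuperpixelMap
            sp = SuperpixelMap(labels, 8, 8, 4, 4)
            b = np.argwhere(classify_boundary(sp).boundary_mask).astype(float)
            return cKDTree(b).query(edge)[0].mean()

        grid = init_grid(32, 32, 8, 8)
        final, _ = extract_superpixels(img, 8, 8)
        assert mean_dist(final.labels) <= mean_dist(grid.labels)

    def test_refine_mode_returns_plain_labels(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        labels, _ = extract_superpixels(img, 4, 4, refine=True)
        assert isinstance(labels, np.ndarray)


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        img = rng.integers(0, 256, size=(24, 24))
        spmap, _ = extract_superpixels(img, 6, 6)
        save_superpixel_map(spmap, tmp_path / "sp.png")
        back = load_superpixel_map(tmp_path / "sp.png")
        np.testing.assert_array_equal(back.labels, spmap.labels)
        assert (back.grid_w, back.grid_h) == (6, 6)


class TestEstimator:
    def test_fit_sets_attributes_and_clones(self, phantom_pair):
        from sklearn.base import clone

        image, _ = phantom_pair
        est = UseqSuperpixels(grid_w=32, grid_h=32)
        est2 = clone(est).fit(image)
        assert est2.labels_.shape == image.shape
        assert est2.segmentation_.n_superpixels == 1024
        assert est2.get_params()["n_bins"] == 16
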