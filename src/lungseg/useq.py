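"""USEQ superpixel extraction.

USEQ (ultrafast superpixel extraction via quantization) builds superpixels in
a fixed number of non-iterative passes:

1. *Spatial quantization* — partition the image into a regular grid of
   ``grid_h x grid_w`` rectangular cells, one initial superpixel per cell.
2. *Color quantization* — histogram each cell's intensities into uniform bins
   and take the midpoint of the most populated bin as the cell's dominant
   color; record the cell centroid.
3. *MAP pixel reassignment* — a single maximum-a-posteriori pass moves each
   pixel to the best of its current superpixel and that superpixel's grid
   neighbors, scoring candidates by a weighted sum of squared spatial distance
   to the candidate centroid and squared intensity distance to the candidate
   dominant color. This snaps superpixel boundaries onto image edges.
4. *Neighborhood refinement* — merging small superpixels into similar
   neighbors. Disabled by default here: resizing requires exactly one
   superpixel per low-resolution pixel, and merging would break that
   bijection. Enable via ``refine=True`` for standalone superpixel use only.

There is no randomness anywhere: identical inputs give identical maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .image_model import GrayImage

__all__ = [
    "SuperpixelMap",
    "SuperpixelStats",
    "Adjacency",
    "init_grid",
    "adjacency",
    "quantize_colors",
    "map_reassign",
    "extract_superpixels",
    "save_superpixel_map",
    "load_superpixel_map",
    "UseqSuperpixels",
]


@dataclass(frozen=True)
class SuperpixelMap:
    """Per-pixel superpixel indices plus the low-resolution grid geometry.

    ``n_superpixels == grid_w * grid_h`` always holds: superpixel ``i``
    corresponds to low-res pixel ``(i // grid_w, i % grid_w)``. A superpixel
    may own zero pixels after MAP reassignment; :meth:`empty_superpixels`
    exposes those for downstream fallback handling.
    """

    labels: np.ndarray
    grid_w: int
    grid_h: int
    cell_w: int
    cell_h: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("superpixel labels must be 2-D")
        object.__setattr__(self, "labels", arr.astype(np.int64, copy=False))

    @property
    def n_superpixels(self) -> int:
        return self.grid_w * self.grid_h

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_superpixels)

    def empty_superpixels(self) -> np.ndarray:
        return np.flatnonzero(self.pixel_counts() == 0)


@dataclass(frozen=True)
class SuperpixelStats:
    """Per-superpixel centroid (row, col), dominant color and pixel count."""

    centroids: np.ndarray  # (n, 2) float, (row, col)
    dominant: np.ndarray  # (n,) float
    counts: np.ndarray  # (n,) int

    @property
    def n_superpixels(self) -> int:
        return len(self.counts)


class Adjacency:
    """Symmetric, irreflexive neighbor relation over superpixel indices."""

    def __init__(self, n: int, pairs: np.ndarray):
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        keep = lo != hi
        uniq = np.unique(np.stack([lo[keep], hi[keep]], axis=1), axis=0)
        self.n = n
        self._pairs = uniq
        nbrs: list[list[int]] = [[] for _ in range(n)]
        for a, b in uniq:
            nbrs[a].append(int(b))
            nbrs[b].append(int(a))
        self._neighbors = [np.array(sorted(v), dtype=np.int64) for v in nbrs]

    def neighbors(self, i: int) -> np.ndarray:
        return self._neighbors[i]

    def is_adjacent(self, i: int, j: int) -> bool:
        return j in self._neighbors[i]

    @property
    def pairs(self) -> np.ndarray:
        return self._pairs

    def degree(self) -> np.ndarray:
        return np.array([len(v) for v in self._neighbors])


def _as_values(image) -> np.ndarray:
    if isinstance(image, GrayImage):
        return image.values
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    return arr


def init_grid(W: int, H: int, grid_w: int, grid_h: int) -> SuperpixelMap:
    """Spatial quantization: partition the image into grid cells.

    Cell sizes are ``ceil(W / grid_w)`` by ``ceil(H / grid_h)``; edge cells
    absorb the remainder (the last cell along each axis may be smaller). The
    assignment is equivalent to nearest-grid-center with ties toward the
    lower index.
    """
    if not (1 <= grid_w <= W and 1 <= grid_h <= H):
        raise ValueError(
            f"grid {grid_w}x{grid_h} incompatible with image {W}x{H}"
        )
    cell_w = -(-W // grid_w)
    cell_h = -(-H // grid_h)
    cols = np.minimum(np.arange(W) // cell_w, grid_w - 1)
    rows = np.minimum(np.arange(H) // cell_h, grid_h - 1)
    labels = rows[:, None] * grid_w + cols[None, :]
    return SuperpixelMap(labels, grid_w=grid_w, grid_h=grid_h,
                         cell_w=cell_w, cell_h=cell_h)


def adjacency(spmap: SuperpixelMap) -> Adjacency:
    """Neighbor relation: sp_i ~ sp_j iff some pixel of i 4-touches one of j."""
    lab = spmap.labels
    h_pairs = np.stack([lab[:, :-1].ravel(), lab[:, 1:].ravel()], axis=1)
    v_pairs = np.stack([lab[:-1, :].ravel(), lab[1:, :].ravel()], axis=1)
    return Adjacency(spmap.n_superpixels, np.concatenate([h_pairs, v_pairs]))


def _grid_adjacency(grid_w: int, grid_h: int) -> Adjacency:
    gy, gx = np.mgrid[0:grid_h, 0:grid_w]
    idx = gy * grid_w + gx
    h_pairs = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    v_pairs = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    return Adjacency(grid_w * grid_h,
                     np.concatenate([h_pairs, v_pairs]) if h_pairs.size + v_pairs.size
                     else np.empty((0, 2), dtype=np.int64))


def _nearest_nonempty_donor(counts: np.ndarray, grid_w: int, grid_h: int) -> np.ndarray:
    """For each superpixel, itself if non-empty else the nearest non-empty
    grid neighbor (Euclidean grid distance, lowest index on ties)."""
    n = grid_w * grid_h
    donor = np.arange(n)
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return donor
    nonempty = np.flatnonzero(counts > 0)
    if nonempty.size == 0:
        raise ValueError("all superpixels are empty")
    gy, gx = np.divmod(np.arange(n), grid_w)
    for i in empty:
        d2 = (gy[nonempty] - gy[i]) ** 2 + (gx[nonempty] - gx[i]) ** 2
        donor[i] = nonempty[np.argmin(d2)]  # argmin takes lowest index on ties
    return donor


def quantize_colors(image, spmap: SuperpixelMap, n_bins: int = 16,
                    max_value: int = 255) -> SuperpixelStats:
    """Color quantization: per-superpixel dominant color and centroid.

    Intensities are histogrammed into ``n_bins`` uniform bins over
    ``[0, max_value]``; the dominant color is the midpoint of the most
    populated bin (ties toward the lower bin). Empty superpixels take the
    geometric center of their grid cell as centroid and the dominant color of
    the nearest non-empty grid neighbor.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = _as_values(image)
    if vals.shape != spmap.shape:
        raise ValueError("image and superpixel map shapes differ")
    n = spmap.n_superpixels
    lab = spmap.labels.ravel()
    bin_width = (max_value + 1) / n_bins
    bins = np.minimum((vals.ravel() / bin_width).astype(np.int64), n_bins - 1)
    hist = np.zeros((n, n_bins), dtype=np.int64)
    np.add.at(hist, (lab, bins), 1)
    dominant_bin = np.argmax(hist, axis=1)  # lowest bin wins ties
    dominant = (dominant_bin + 0.5) * bin_width

    counts = np.bincount(lab, minlength=n)
    rr, cc = np.mgrid[0:vals.shape[0], 0:vals.shape[1]]
    sum_r = np.bincount(lab, weights=rr.ravel(), minlength=n)
    sum_c = np.bincount(lab, weights=cc.ravel(), minlength=n)
    safe = np.maximum(counts, 1)
    centroids = np.stack([sum_r / safe, sum_c / safe], axis=1)

    empty = np.flatnonzero(counts == 0)
    if empty.size:
        donor = _nearest_nonempty_donor(counts, spmap.grid_w, spmap.grid_h)
        gy, gx = np.divmod(empty, spmap.grid_w)
        # grid-cell geometric center for the emptied cell
        r0 = gy * spmap.cell_h
        c0 = gx * spmap.cell_w
        r1 = np.minimum(r0 + spmap.cell_h, vals.shape[0])
        c1 = np.minimum(c0 + spmap.cell_w, vals.shape[1])
        centroids[empty, 0] = (r0 + np.maximum(r1, r0 + 1) - 1) / 2.0
        centroids[empty, 1] = (c0 + np.maximum(c1, c0 + 1) - 1) / 2.0
        dominant[empty] = dominant[donor[empty]]
    return SuperpixelStats(centroids=centroids, dominant=dominant, counts=counts)


def map_reassign(image, spmap: SuperpixelMap, stats: SuperpixelStats,
                 adj: Adjacency, lambda_s: float, lambda_c: float) -> SuperpixelMap:
    """Single-pass MAP pixel label reassignment.

    Each pixel ``p`` currently in superpixel ``i`` is moved to the candidate
    ``j`` in ``{i} ∪ neighbors(i)`` minimising::

        lambda_s * ||p - centroid_j||^2 + lambda_c * (I(p) - dominant_j)^2

    Ties are broken toward the current label, then the lower index. The pass
    is non-iterative; the superpixel count is unchanged, though a superpixel
    may end up owning no pixels.
    """
    if lambda_s < 0 or lambda_c < 0:
        raise ValueError("lambda_s and lambda_c must be non-negative")
    vals = _as_values(image).astype(np.float64)
    if vals.shape != spmap.shape:
        raise ValueError("image and superpixel map shapes differ")
    n = spmap.n_superpixels
    max_deg = int(adj.degree().max(initial=0))
    # candidate table: current label first, then neighbors in ascending order,
    # padded with the current label (harmless duplicates)
    cand = np.tile(np.arange(n)[:, None], (1, max_deg + 1))
    for i in range(n):
        nb = adj.neighbors(i)
        cand[i, 1:1 + len(nb)] = nb

    lab = spmap.labels.ravel()
    H, W = spmap.shape
    rr, cc = np.mgrid[0:H, 0:W]
    px_cand = cand[lab]  # (N, K)
    dy = rr.ravel()[:, None] - stats.centroids[px_cand, 0]
    dx = cc.ravel()[:, None] - stats.centroids[px_cand, 1]
    dc = vals.ravel()[:, None] - stats.dominant[px_cand]
    cost = lambda_s * (dy * dy + dx * dx) + lambda_c * (dc * dc)
    best = np.argmin(cost, axis=1)  # first minimum: current label wins ties
    new_lab = px_cand[np.arange(lab.size), best].reshape(H, W)
    return SuperpixelMap(new_lab, grid_w=spmap.grid_w, grid_h=spmap.grid_h,
                         cell_w=spmap.cell_w, cell_h=spmap.cell_h)


def _refine_small(image, spmap: SuperpixelMap, stats: SuperpixelStats,
                  min_size: int) -> np.ndarray:
    """Merge superpixels smaller than ``min_size`` into the adjacent
    superpixel with the closest dominant color (standalone use only: the
    result is a plain label array that no longer satisfies the grid
    bijection)."""
    lab = spmap.labels.copy()
    adj = adjacency(spmap)
    counts = spmap.pixel_counts()
    for i in np.flatnonzero((counts > 0) & (counts < min_size)):
        nb = adj.neighbors(i)
        if nb.size == 0:
            continue
        target = nb[np.argmin(np.abs(stats.dominant[nb] - stats.dominant[i]))]
        lab[lab == i] = target
    return lab


def default_lambdas(spmap: SuperpixelMap, max_value: int = 255) -> tuple[float, float]:
    """Scale-free default weights: spatial term normalised by the cell area,
    color term by the squared intensity range."""
    return 1.0 / (spmap.cell_w * spmap.cell_h), 1.0 / float(max_value) ** 2


def extract_superpixels(image, grid_w: int, grid_h: int, *,
                        n_bins: int = 16, lambda_s: float | None = None,
                        lambda_c: float | None = None, refine: bool = False,
                        min_size: int | None = None):
    """Full USEQ extraction: grid init, color quantization, MAP reassignment.

    Returns ``(SuperpixelMap, SuperpixelStats)`` with stats refreshed on the
    final map. With ``refine=True`` the fourth USEQ step (merging small
    superpixels) is applied and a plain label array is returned instead of a
    :class:`SuperpixelMap` — refinement breaks the superpixel/low-res-pixel
    bijection the resizing framework depends on.
    """
    vals = _as_values(image)
    max_value = image.max_value if isinstance(image, GrayImage) else 255
    H, W = vals.shape
    grid = init_grid(W, H, grid_w, grid_h)
    stats0 = quantize_colors(vals, grid, n_bins=n_bins, max_value=max_value)
    ls, lc = default_lambdas(grid, max_value)
    if lambda_s is not None:
        ls = lambda_s
    if lambda_c is not None:
        lc = lambda_c
    adj = _grid_adjacency(grid_w, grid_h)
    spmap = map_reassign(vals, grid, stats0, adj, ls, lc)
    stats = quantize_colors(vals, spmap, n_bins=n_bins, max_value=max_value)
    if refine:
        if min_size is None:
            min_size = max(1, (grid.cell_w * grid.cell_h) // 4)
        return _refine_small(vals, spmap, stats, min_size), stats
    return spmap, stats


# -- serialization -----------------------------------------------------------

def save_superpixel_map(spmap: SuperpixelMap, path) -> None:
    """Write labels as 16-bit grayscale PNG plus a JSON geometry sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    if spmap.n_superpixels > 0xFFFF:
        raise ValueError("more than 65535 superpixels cannot be stored as 16-bit PNG")
    iio.imwrite(path, spmap.labels.astype(np.uint16))
    sidecar = {"grid_w": spmap.grid_w, "grid_h": spmap.grid_h,
               "cell_w": spmap.cell_w, "cell_h": spmap.cell_h}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_superpixel_map(path) -> SuperpixelMap:
    import imageio.v3 as iio

    path = Path(path)
    labels = np.asarray(iio.imread(path)).astype(np.int64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SuperpixelMap(labels, **meta)


class UseqSuperpixels(ClusterMixin, BaseEstimator):
    """USEQ superpixel extraction as a clustering estimator.

    Parameters
    ----------
    grid_w, grid_h : int
        Low-resolution grid dimensions; the number of superpixels is their
        product and each superpixel corresponds to one low-res pixel.
    n_bins : int, default=16
        Uniform intensity bins for color quantization.
    lambda_s, lambda_c : float or None
        Spatial / color weights of the MAP reassignment score. ``None``
        selects the scale-free defaults ``1/(cell_w*cell_h)`` and
        ``1/max_value**2``.
    refine : bool, default=False
        Apply the small-superpixel merging step (standalone use only).

    Attributes
    ----------
    labels_ : ndarray of shape (H, W)
        Superpixel index per pixel.
    segmentation_ : SuperpixelMap
        Labels plus grid geometry (absent when ``refine=True``).
    stats_ : SuperpixelStats
        Per-superpixel centroids, dominant colors and counts.
    """

    def __init__(self, grid_w: int = 64, grid_h: int = 64, *, n_bins: int = 16,
                 lambda_s: float | None = None, lambda_c: float | None = None,
                 refine: bool = False):
        self.grid_w = grid_w
        self.grid_h = grid_h
        self.n_bins = n_bins
        self.lambda_s = lambda_s
        self.lambda_c = lambda_c
        self.refine = refine

    def fit(self, X, y=None):
        result, stats = extract_superpixels(
            X, self.grid_w, self.grid_h, n_bins=self.n_bins,
            lambda_s=self.lambda_s, lambda_c=self.lambda_c, refine=self.refine)
        if self.refine:
            self.labels_ = result
        else:
            self.segmentation_ = result
            self.labels_ = result.labels
        self.stats_ = stats
        return self
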