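"""Superpixel resizing: boundary-preserving downsampling and upsampling.

The framework decomposes an image ``I = H + B`` into a homogeneous part and a
boundary part. Given a superpixel map in bijection with the low-resolution
grid, each superpixel's pixels split into

* the *boundary set* ``sp_i^B`` — pixels with a 4-neighbor in a different
  superpixel (distance-1 contact), and
* the *homogeneous set* ``sp_i^H`` — the rest.

Downsampling (``F_D``) assigns each low-res pixel the mean intensity of its
superpixel's homogeneous set, so object boundaries do not bleed into the
low-res values. The original intensities of all boundary pixels are stored.
Upsampling (``F_U``) paints every homogeneous pixel with its superpixel's
low-res value and restores every boundary pixel from the store, so edges come
back at full resolution exactly where they were.

Baseline nearest / bilinear / bicubic resizers are provided for comparison;
they use the center-aligned coordinate convention and round half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .image_model import GrayImage, LabelMask
from .useq import (SuperpixelMap, SuperpixelStats, _as_values,
                   _nearest_nonempty_donor, extract_superpixels)

__all__ = [
    "BoundaryStore",
    "LowResImage",
    "LowResMask",
    "classify_boundary",
    "downsample_image",
    "downsample_mask",
    "upsample_labels",
    "upsample_image",
    "baseline_resize",
    "roundtrip",
    "grid_dims_from_rate",
    "SuperpixelResizer",
]

_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class BoundaryStore:
    """Partition of every superpixel into homogeneous and boundary pixels,
    plus the original intensities at boundary positions once captured."""

    spmap: SuperpixelMap
    boundary_mask: np.ndarray  # (H, W) bool, True on union of sp_i^B
    values: np.ndarray | None = None  # original intensities, valid on boundary

    @property
    def captured(self) -> bool:
        return self.values is not None

    def capture(self, image) -> "BoundaryStore":
        vals = _as_values(image)
        if vals.shape != self.spmap.shape:
            raise ValueError("image and superpixel map shapes differ")
        self.values = vals.copy()
        return self

    def boundary_of(self, i: int) -> np.ndarray:
        """(k, 2) array of (row, col) boundary positions of superpixel i."""
        return np.argwhere((self.spmap.labels == i) & self.boundary_mask)

    def homogeneous_of(self, i: int) -> np.ndarray:
        return np.argwhere((self.spmap.labels == i) & ~self.boundary_mask)


def classify_boundary(spmap: SuperpixelMap) -> BoundaryStore:
    """Split each superpixel into boundary and homogeneous pixel sets.

    A pixel is a boundary pixel iff one of its 4-neighbors carries a
    different superpixel label; the image border itself does not create
    boundary pixels.
    """
    lab = spmap.labels
    b = np.zeros(lab.shape, dtype=bool)
    b[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    b[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    b[:-1, :] |= lab[:-1, :] != lab[1:, :]
    b[1:, :] |= lab[1:, :] != lab[:-1, :]
    return BoundaryStore(spmap=spmap, boundary_mask=b)


@dataclass(frozen=True)
class LowResImage:
    """Downsampled raster; pixel ``(gy, gx)`` corresponds to superpixel
    ``gy * grid_w + gx`` of ``spmap``."""

    values: np.ndarray
    spmap: SuperpixelMap
    bit_depth: int = 8

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LowResMask:
    labels: np.ndarray
    spmap: SuperpixelMap
    n_classes: int = 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def downsample_image(image, spmap: SuperpixelMap,
                     store: BoundaryStore) -> LowResImage:
    """F_D: low-res pixel value = mean intensity over the homogeneous set.

    Fallbacks: a superpixel whose homogeneous set is empty uses the mean over
    all of its pixels; a superpixel owning no pixels at all takes the value of
    its nearest non-empty grid neighbor. The store captures the original
    boundary intensities as a side effect. Means are accumulated in floating
    point and rounded half-up to the image bit depth.
    """
    vals = _as_values(image).astype(np.float64)
    if vals.shape != spmap.shape:
        raise ValueError("image and superpixel map shapes differ")
    if store.spmap is not spmap and not np.array_equal(store.spmap.labels, spmap.labels):
        raise ValueError("boundary store was built from a different map")
    store.capture(vals.astype(np.int64))

    n = spmap.n_superpixels
    lab = spmap.labels.ravel()
    hom = ~store.boundary_mask.ravel()
    v = vals.ravel()

    hom_counts = np.bincount(lab[hom], minlength=n)
    hom_sums = np.bincount(lab[hom], weights=v[hom], minlength=n)
    all_counts = np.bincount(lab, minlength=n)
    all_sums = np.bincount(lab, weights=v, minlength=n)

    out = np.empty(n, dtype=np.float64)
    use_hom = hom_counts > 0
    out[use_hom] = hom_sums[use_hom] / hom_counts[use_hom]
    use_all = (~use_hom) & (all_counts > 0)
    out[use_all] = all_sums[use_all] / all_counts[use_all]
    donor = _nearest_nonempty_donor(all_counts, spmap.grid_w, spmap.grid_h)
    empty = all_counts == 0
    out[empty] = out[donor[empty]]

    bit_depth = image.bit_depth if isinstance(image, GrayImage) else 8
    out = np.clip(_round_half_up(out), 0, (1 << bit_depth) - 1).astype(np.int64)
    return LowResImage(out.reshape(spmap.grid_h, spmap.grid_w), spmap,
                       bit_depth=bit_depth)


def downsample_mask(mask, spmap: SuperpixelMap, n_classes: int = 2) -> LowResMask:
    """Per-superpixel plurality vote over all of the superpixel's pixels.

    Ties go to the lower label (for binary masks: background). Superpixels
    with no pixels take the vote of their nearest non-empty grid neighbor.
    """
    if isinstance(mask, LabelMask):
        lab_vals, n_classes = mask.labels, mask.n_classes
    else:
        lab_vals = np.asarray(mask, dtype=np.int64)
    if lab_vals.shape != spmap.shape:
        raise ValueError("mask and superpixel map shapes differ")
    n = spmap.n_superpixels
    sp = spmap.labels.ravel()
    hist = np.zeros((n, n_classes), dtype=np.int64)
    np.add.at(hist, (sp, lab_vals.ravel()), 1)
    winner = np.argmax(hist, axis=1)  # lower label wins ties
    counts = hist.sum(axis=1)
    donor = _nearest_nonempty_donor(counts, spmap.grid_w, spmap.grid_h)
    empty = counts == 0
    winner[empty] = winner[donor[empty]]
    return LowResMask(winner.reshape(spmap.grid_h, spmap.grid_w), spmap,
                      n_classes=n_classes)


def upsample_labels(lowres: LowResMask, spmap: SuperpixelMap,
                    store: BoundaryStore | None = None) -> LabelMask:
    """Every pixel of superpixel i — homogeneous and boundary alike —
    receives the label of low-res pixel i. Background low-res pixels yield
    background at full resolution.

    The stored boundary intensities are not used for labels: they are
    graylevels, which carry no class information for a mask.
    """
    if lowres.shape != (spmap.grid_h, spmap.grid_w):
        raise ValueError("low-res mask does not match the superpixel grid")
    full = lowres.labels.ravel()[spmap.labels.ravel()].reshape(spmap.shape)
    return LabelMask(full, n_classes=lowres.n_classes)


def upsample_image(lowres: LowResImage, spmap: SuperpixelMap,
                   store: BoundaryStore,
                   background_lowres: np.ndarray | None = None) -> GrayImage:
    """F_U: homogeneous pixels take their superpixel's low-res value;
    boundary pixels are restored from the stored original intensities.

    When ``background_lowres`` (a boolean low-res mask) is given, pixels of
    superpixels flagged as background are zeroed.
    """
    if lowres.shape != (spmap.grid_h, spmap.grid_w):
        raise ValueError("low-res image does not match the superpixel grid")
    if not store.captured:
        raise ValueError("boundary store has no captured intensities; "
                         "run downsample_image (or store.capture) first")
    full = lowres.values.ravel()[spmap.labels.ravel()].reshape(spmap.shape)
    full = full.copy()
    full[store.boundary_mask] = store.values[store.boundary_mask]
    if background_lowres is not None:
        bg = np.asarray(background_lowres, dtype=bool).ravel()
        full[bg[spmap.labels]] = 0
    return GrayImage(full.astype(np.int64), bit_depth=lowres.bit_depth)


def baseline_resize(image, out_w: int, out_h: int, method: str) -> GrayImage:
    """Standard separable interpolation to ``out_h x out_w``.

    ``method`` is one of ``nearest``, ``bilinear``, ``bicubic``. Output
    coordinates map to input coordinates by the center-aligned rule
    ``x_in = (x_out + 0.5) * W_in / W_out - 0.5``; values are clipped to the
    intensity range and rounded half-up. As in mainstream resize
    implementations, bilinear and bicubic downsampling apply a Gaussian
    anti-aliasing prefilter (sigma = (factor - 1) / 2 per axis); nearest
    neighbor never filters and upsampling never filters.
    """
    if method not in _ORDERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_ORDERS)}")
    if out_w < 1 or out_h < 1:
        raise ValueError("output dimensions must be >= 1")
    vals = _as_values(image).astype(np.float64)
    bit_depth = image.bit_depth if isinstance(image, GrayImage) else 8
    H, W = vals.shape
    if method != "nearest":
        sigma = (max((H / out_h - 1) / 2, 0), max((W / out_w - 1) / 2, 0))
        if sigma[0] > 0 or sigma[1] > 0:
            vals = ndimage.gaussian_filter(vals, sigma, mode="nearest")
    r = (np.arange(out_h) + 0.5) * (H / out_h) - 0.5
    c = (np.arange(out_w) + 0.5) * (W / out_w) - 0.5
    rr, cc = np.meshgrid(r, c, indexing="ij")
    out = ndimage.map_coordinates(vals, [rr, cc], order=_ORDERS[method],
                                  mode="nearest")
    out = np.clip(_round_half_up(out), 0, (1 << bit_depth) - 1).astype(np.int64)
    return GrayImage(out, bit_depth=bit_depth)


def grid_dims_from_rate(W: int, H: int, rate: float) -> tuple[int, int]:
    """Low-res dimensions from a linear downsampling rate (round half-up)."""
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    gw = int(_round_half_up(W * rate))
    gh = int(_round_half_up(H * rate))
    if gw < 1 or gh < 1:
        raise ValueError(f"rate {rate} degenerates the {W}x{H} image")
    return gw, gh


def roundtrip(image, rate: float, method: str = "useq", **useq_params):
    """Downsample to ``round(W*rate) x round(H*rate)`` and back; return the
    reconstruction and its PSNR against the original (math.inf when the
    round trip is bit-exact)."""
    from .metrics import psnr

    vals = _as_values(image)
    bit_depth = image.bit_depth if isinstance(image, GrayImage) else 8
    H, W = vals.shape
    gw, gh = grid_dims_from_rate(W, H, rate)
    if method == "useq":
        spmap, _ = extract_superpixels(image, gw, gh, **useq_params)
        store = classify_boundary(spmap)
        low = downsample_image(image, spmap, store)
        recon = upsample_image(low, spmap, store)
    elif method in _ORDERS:
        low = baseline_resize(image, gw, gh, method)
        recon = baseline_resize(low, W, H, method)
    else:
        raise ValueError(f"unknown method {method!r}")
    ref = image if isinstance(image, GrayImage) else GrayImage(vals, bit_depth=bit_depth)
    return recon, psnr(ref, recon)


class SuperpixelResizer(TransformerMixin, BaseEstimator):
    """Boundary-preserving image resizer as a transformer.

    ``fit(X)`` extracts USEQ superpixels of the input image at the grid size
    implied by ``rate``; ``transform(X)`` downsamples (capturing boundary
    intensities); ``inverse_transform(Xd)`` upsamples back to full
    resolution, restoring boundaries exactly. Mask counterparts are
    :meth:`transform_mask` and :meth:`inverse_transform_labels`.

    Parameters
    ----------
    rate : float, default=0.25
        Linear downsampling rate in (0, 1].
    n_bins, lambda_s, lambda_c :
        USEQ parameters, see :class:`~lungseg.useq.UseqSuperpixels`.

    Attributes
    ----------
    spmap_ : SuperpixelMap
    store_ : BoundaryStore
    stats_ : SuperpixelStats
    """

    def __init__(self, rate: float = 0.25, *, n_bins: int = 16,
                 lambda_s: float | None = None, lambda_c: float | None = None):
        self.rate = rate
        self.n_bins = n_bins
        self.lambda_s = lambda_s
        self.lambda_c = lambda_c

    def fit(self, X, y=None):
        vals = _as_values(X)
        H, W = vals.shape
        gw, gh = grid_dims_from_rate(W, H, self.rate)
        self.spmap_, self.stats_ = extract_superpixels(
            X, gw, gh, n_bins=self.n_bins,
            lambda_s=self.lambda_s, lambda_c=self.lambda_c)
        self.store_ = classify_boundary(self.spmap_)
        return self

    def transform(self, X) -> np.ndarray:
        low = downsample_image(X, self.spmap_, self.store_)
        self.bit_depth_ = low.bit_depth
        return low.values

    def inverse_transform(self, Xd) -> np.ndarray:
        low = LowResImage(np.asarray(Xd, dtype=np.int64), self.spmap_,
                          bit_depth=getattr(self, "bit_depth_", 8))
        return upsample_image(low, self.spmap_, self.store_).values

    def transform_mask(self, mask) -> np.ndarray:
        return downsample_mask(mask, self.spmap_).labels

    def inverse_transform_labels(self, labels, n_classes: int = 2) -> np.ndarray:
        low = LowResMask(np.asarray(labels, dtype=np.int64), self.spmap_,
                         n_classes=n_classes)
        return upsample_labels(low, self.spmap_, self.store_).labels
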