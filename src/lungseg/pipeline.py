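"""End-to-end lung field segmentation with superpixel resizing.

The inference path for one image:

1. extract USEQ superpixels at the grid size implied by the downsampling
   rate (one superpixel per low-resolution pixel);
2. downsample the image with the boundary-preserving interpolation,
   storing boundary pixel intensities;
3. segment the low-resolution image;
4. upsample the low-resolution mask by painting every pixel of each
   superpixel with its superpixel's label — boundaries land exactly on the
   superpixel boundaries, which adhere to the image edges;
5. post-process: keep the two largest components, fill holes.

Training downsamples every image and mask the same way and fits the
segmenter on the low-resolution pairs. Superpixels are always recomputed on
the image being processed, never reused across images.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone

from .image_model import GrayImage, LabelMask
from .metrics import evaluate_pair, mean_finite_psnr, psnr
from .postprocess import postprocess as _postprocess
from .resize import (baseline_resize, classify_boundary, downsample_image,
                     downsample_mask, grid_dims_from_rate, roundtrip,
                     upsample_labels)
from .segment import ThresholdSegmenter
from .useq import _as_values, extract_superpixels

__all__ = [
    "run_pipeline",
    "train_pipeline",
    "compare_interpolations",
    "LungFieldPipeline",
]


def _decompose(image, rate: float, useq_params: dict | None):
    vals = _as_values(image)
    H, W = vals.shape
    gw, gh = grid_dims_from_rate(W, H, rate)
    spmap, _ = extract_superpixels(image, gw, gh, **(useq_params or {}))
    store = classify_boundary(spmap)
    low = downsample_image(image, spmap, store)
    return spmap, store, low


def run_pipeline(image, segmenter, rate: float = 0.25,
                 useq_params: dict | None = None, *,
                 apply_postprocess: bool = True,
                 keep_intermediates: bool = False):
    """Segment one image at full resolution through the low-res detour.

    Returns the final :class:`LabelMask`; with ``keep_intermediates=True``
    a ``(mask, intermediates)`` tuple where the dict holds the superpixel
    map, boundary store, low-res image and low-res mask.
    """
    from .resize import LowResMask

    spmap, store, low = _decompose(image, rate, useq_params)
    low_image = GrayImage(low.values, bit_depth=low.bit_depth)
    low_mask = segmenter.predict(low_image)
    lr_mask = LowResMask(low_mask.labels, spmap, n_classes=low_mask.n_classes)
    full = upsample_labels(lr_mask, spmap, store)
    if apply_postprocess:
        full = _postprocess(full)
    if keep_intermediates:
        return full, {"spmap": spmap, "store": store, "lowres_image": low,
                      "lowres_mask": lr_mask}
    return full


def train_pipeline(dataset, segmenter, rate: float = 0.25,
                   useq_params: dict | None = None):
    """Fit the segmenter on superpixel-downsampled (image, mask) pairs.

    ``dataset`` is a sequence of ``(GrayImage, LabelMask)``. Segmenters
    without anything to learn (e.g. the threshold reference) are fitted as a
    no-op. Returns the fitted segmenter.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    low_images, low_masks = [], []
    for image, mask in dataset:
        spmap, store, low = _decompose(image, rate, useq_params)
        low_images.append(low.values)
        low_masks.append(downsample_mask(mask, spmap).labels)
    return segmenter.fit(low_images, low_masks)


def _baseline_segmentation_path(image, mask_truth, segmenter, rate, method):
    vals = _as_values(image)
    H, W = vals.shape
    gw, gh = grid_dims_from_rate(W, H, rate)
    low = baseline_resize(image, gw, gh, method)
    low_mask = segmenter.predict(low)
    up = baseline_resize(GrayImage(low_mask.labels * 255, bit_depth=8), W, H, method)
    full = LabelMask((up.values >= 128).astype(np.int64))
    return _postprocess(full)


def compare_interpolations(dataset, rates=(0.125, 0.25, 0.5),
                           methods=("useq", "nearest", "bilinear", "bicubic"),
                           segmenter=None, useq_params: dict | None = None):
    """Round-trip PSNR (and optionally segmentation quality) per method/rate.

    Returns a list of row dicts with keys ``method``, ``rate``,
    ``mean_psnr`` (mean over finite cases; ``inf`` if every round trip was
    bit-exact), ``n_lossless`` and, when a segmenter is given and the
    dataset carries masks, ``mean_dsc`` / ``mean_mhd`` of the full-resolution
    segmentations against ground truth.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    rows = []
    for method in methods:
        for rate in rates:
            psnrs, dscs, mhds = [], [], []
            for item in dataset:
                image, mask = item if isinstance(item, tuple) else (item, None)
                _, p = roundtrip(image, rate, method, **(useq_params or {}))
                psnrs.append(p)
                if segmenter is not None and mask is not None:
                    if method == "useq":
                        pred = run_pipeline(image, segmenter, rate, useq_params)
                    else:
                        pred = _baseline_segmentation_path(
                            image, mask, segmenter, rate, method)
                    rep = evaluate_pair(pred, mask)
                    dscs.append(rep.dsc)
                    mhds.append(rep.mhd)
            mean_psnr, n_inf = mean_finite_psnr(psnrs)
            row = {"method": method, "rate": rate,
                   "mean_psnr": mean_psnr, "n_lossless": n_inf}
            if dscs:
                row["mean_dsc"] = float(np.mean(dscs))
                row["mean_mhd"] = float(np.mean(mhds))
            rows.append(row)
    return rows


class LungFieldPipeline(BaseEstimator):
    """The full segmentation pipeline as an estimator.

    Parameters
    ----------
    segmenter : estimator or None
        Low-resolution segmenter with ``fit(images, masks)`` and
        ``predict(image)``; defaults to :class:`ThresholdSegmenter`.
    rate : float, default=0.25
        Linear downsampling rate.
    postprocess : bool, default=True
        Apply largest-two-components + hole filling to the output.
    useq_params : dict or None
        Extra USEQ parameters (``n_bins``, ``lambda_s``, ``lambda_c``).
    """

    def __init__(self, segmenter=None, rate: float = 0.25,
                 postprocess: bool = True, useq_params: dict | None = None):
        self.segmenter = segmenter
        self.rate = rate
        self.postprocess = postprocess
        self.useq_params = useq_params

    def _segmenter(self):
        return clone(self.segmenter) if self.segmenter is not None \
            else ThresholdSegmenter()

    def fit(self, X, y):
        """Fit the segmenter on downsampled pairs; X and y are matching
        sequences of images and masks."""
        self.segmenter_ = train_pipeline(list(zip(X, y)), self._segmenter(),
                                         self.rate, self.useq_params)
        return self

    def predict(self, image) -> LabelMask:
        seg = getattr(self, "segmenter_", None)
        if seg is None:
            seg = self._segmenter().fit()
        return run_pipeline(image, seg, self.rate, self.useq_params,
                            apply_postprocess=self.postprocess)
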