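"""Segmentation and reconstruction quality metrics.

Overlap metrics (DSC, sensitivity, specificity, Jaccard) are computed from
the pixel confusion counts of a prediction/ground-truth pair. Boundary
metrics (MHD, MBD) compare the inner boundaries of the two masks with
nearest-point Euclidean distances. PSNR measures reconstruction fidelity of a
resizing round trip; a bit-exact reconstruction has zero MSE, for which PSNR
is reported as the ``math.inf`` sentinel (and excluded from averages by the
reporting helpers).

Conventions for degenerate inputs, which real evaluations never hit but
tests do: when a fraction metric's denominator is zero the metric is 1
(an empty prediction of an empty truth is perfect); boundary distances on an
empty boundary raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .image_model import GrayImage, LabelMask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "dsc",
    "sensitivity",
    "specificity",
    "jaccard",
    "boundary_pixels",
    "mhd",
    "mbd",
    "psnr",
    "evaluate_pair",
]


def _as_binary(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        arr = mask.labels
    else:
        arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (labels 0 and 1)")
    return arr.astype(bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts: TP lung hits, FP background called lung,
    FN lung called background, TN background hits."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Named metric collection for one prediction/ground-truth pair."""

    dsc: float
    sensitivity: float
    specificity: float
    jaccard: float
    mhd: float | None = None
    mbd: float | None = None
    psnr: float | None = None


def confusion(pred, truth) -> ConfusionCounts:
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, 2TP / (2TP + FP + FN)."""
    return _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _ratio(float(c.tp), float(c.tp + c.fn))


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return _ratio(float(c.tn), float(c.tn + c.fp))


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard overlap index, TP / (TP + FP + FN)."""
    return _ratio(float(c.tp), float(c.tp + c.fp + c.fn))


def boundary_pixels(mask) -> np.ndarray:
    """Inner boundary: foreground pixels with a 4-neighbor background pixel
    or lying on the image border. Returns an (k, 2) array of (row, col)."""
    m = _as_binary(mask)
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def _min_dists(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """For each point of src, Euclidean distance to the nearest dst point."""
    return cKDTree(dst).query(src)[0]


def mhd(pred, truth, *, symmetric: bool = False) -> float:
    """Modified Hausdorff distance between mask boundaries.

    The directed form (default) averages, over the ground-truth boundary
    points, the distance to the nearest segmentation boundary point. With
    ``symmetric=True`` the maximum of the two directed means is returned
    (the Dubuisson–Jain form).
    """
    bp = boundary_pixels(pred)
    bt = boundary_pixels(truth)
    if len(bp) == 0 or len(bt) == 0:
        raise ValueError(
            "MHD undefined: prediction and ground truth must both have a "
            f"non-empty boundary (got {len(bp)} and {len(bt)} points)")
    d_truth_to_pred = float(_min_dists(bt.astype(float), bp.astype(float)).mean())
    if not symmetric:
        return d_truth_to_pred
    d_pred_to_truth = float(_min_dists(bp.astype(float), bt.astype(float)).mean())
    return max(d_truth_to_pred, d_pred_to_truth)


def mbd(pred, truth, spacing: float = 1.0) -> float:
    """Mean boundary distance: the average of the two directed mean
    nearest-point distances between the boundaries. ``spacing`` converts
    pixels to physical units (mm per pixel)."""
    bp = boundary_pixels(pred).astype(float)
    bt = boundary_pixels(truth).astype(float)
    if len(bp) == 0 or len(bt) == 0:
        raise ValueError("MBD undefined on an empty boundary")
    d1 = _min_dists(bp, bt).mean()
    d2 = _min_dists(bt, bp).mean()
    return float(0.5 * (d1 + d2) * spacing)


def psnr(reference, reconstruction) -> float:
    """Peak signal-to-noise ratio in dB: 20 log10(MAX_I) - 10 log10(MSE).

    MAX_I is taken from the declared bit depth (255 for 8-bit), not the
    observed maximum, so values are comparable across images. Identical
    images (MSE = 0) return ``math.inf``.
    """
    if isinstance(reference, GrayImage):
        ref, max_i = reference.values, reference.max_value
    else:
        ref, max_i = np.asarray(reference), 255
    rec = reconstruction.values if isinstance(reconstruction, GrayImage) else np.asarray(reconstruction)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    if isinstance(reference, GrayImage) and isinstance(reconstruction, GrayImage):
        if reference.bit_depth != reconstruction.bit_depth:
            raise ValueError("bit depths differ")
    diff = ref.astype(np.float64) - rec.astype(np.float64)
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(max_i) - 10.0 * math.log10(mse)


def mean_finite_psnr(values) -> tuple[float, int]:
    """Mean of the finite PSNR values plus the count of bit-exact (infinite)
    cases. All-infinite input yields (inf, n)."""
    vals = list(values)
    inf_count = sum(1 for v in vals if math.isinf(v))
    finite = [v for v in vals if math.isfinite(v)]
    if not finite:
        return math.inf, inf_count
    return float(np.mean(finite)), inf_count


def evaluate_pair(pred, truth, *, spacing: float = 1.0,
                  with_boundary: bool = True) -> MetricReport:
    """All overlap metrics (and boundary metrics unless disabled) for one
    prediction/ground-truth mask pair."""
    c = confusion(pred, truth)
    kwargs = {}
    if with_boundary:
        kwargs["mhd"] = mhd(pred, truth)
        kwargs["mbd"] = mbd(pred, truth, spacing=spacing)
    return MetricReport(dsc=dsc(c), sensitivity=sensitivity(c),
                        specificity=specificity(c), jaccard=jaccard(c), **kwargs)
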