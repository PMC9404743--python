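"""Mask correction after segmentation.

Intensity-driven lung segmentation picks up two kinds of artifacts: dark
regions outside the lungs (e.g. stomach gas) appear as spurious foreground
components, and bright lesions inside a lung punch holes into the true
components. Correction keeps only the two largest foreground components
(the left and right lung fields) and then fills enclosed holes.

Connectivity follows the standard complementary pair: 8-connectivity for
foreground components, 4-connectivity for background holes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_model import LabelMask

__all__ = ["keep_largest_k", "fill_holes", "postprocess"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _as_bool(mask) -> np.ndarray:
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def keep_largest_k(mask, k: int = 2) -> LabelMask:
    """Keep only the ``k`` largest 8-connected foreground components.

    Ties at the cutoff are broken by first appearance in top-left row-major
    scan order (the lower component id of ``scipy.ndimage.label``). Fewer
    than ``k`` components: all are kept.
    """
    m = _as_bool(mask)
    comp, n = ndimage.label(m, structure=_STRUCT8)
    if n <= k:
        return LabelMask(m.astype(np.int64))
    sizes = np.bincount(comp.ravel())[1:]  # sizes[i] = size of component i+1
    # stable sort by descending size keeps lower ids first among equals
    order = np.argsort(-sizes, kind="stable")[:k] + 1
    return LabelMask(np.isin(comp, order).astype(np.int64))


def fill_holes(mask) -> LabelMask:
    """Fill enclosed holes: background regions (4-connectivity) not
    connected to the image border become foreground."""
    m = _as_bool(mask)
    filled = ndimage.binary_fill_holes(m)  # default structure = 4-connectivity
    return LabelMask(filled.astype(np.int64))


def postprocess(mask, k: int = 2) -> LabelMask:
    """Keep the ``k`` largest components, then fill holes. Idempotent."""
    return fill_holes(keep_largest_k(mask, k=k))
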