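"""Core raster types, PNG I/O and bit-depth mapping.

Chest radiographs are single-channel intensity rasters. Source detectors
deliver 12-bit data (4096 graylevels); the processing chain works on 8-bit
images, so a 12-to-8-bit mapping is provided. Binary masks label each pixel
as background (0) or lung field (1); on disk they are stored as viewable
8-bit PNGs with foreground scaled to 255.

Coordinate convention throughout the package: (row, col), 0-based, origin at
the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "LabelMask",
    "read_png",
    "write_png",
    "map_12bit_to_8bit",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D single-channel intensity raster with a declared bit depth.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Integer intensities in ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        Either 8 or 12 (12-bit data is carried in a 16-bit container).
    """

    values: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image must be 2-D and non-empty, got shape {arr.shape}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if arr.min() < 0 or arr.max() > self.max_value:
            raise ValueError(
                f"values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel integer class labels (0 = background, 1 = lung field)."""

    labels: np.ndarray
    n_classes: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"mask must be 2-D and non-empty, got shape {arr.shape}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if arr.min() < 0 or arr.max() >= self.n_classes:
            raise ValueError(f"labels outside [0, {self.n_classes - 1}]")
        object.__setattr__(self, "labels", arr.astype(np.int64, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def read_png(path, *, allow_rgb_conversion: bool = False, as_mask: bool = False):
    """Read a grayscale PNG as a :class:`GrayImage` or :class:`LabelMask`.

    8-bit files yield ``bit_depth=8``; 16-bit files yield ``bit_depth=16``
    (use :func:`map_12bit_to_8bit` after reinterpreting the depth if the file
    carries 12-bit data). Multi-channel files are rejected unless
    ``allow_rgb_conversion`` is set, in which case the luminance mean of
    identical channels is taken.

    With ``as_mask=True`` the on-disk {0, 255} convention is folded back to
    {0, 1} labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if not allow_rgb_conversion:
            raise ValueError(
                f"{path} is multi-channel; pass allow_rgb_conversion=True to "
                "convert to grayscale"
            )
        arr = np.round(arr[..., :3].mean(axis=-1)).astype(arr.dtype)
    if as_mask:
        labels = (arr > 0).astype(np.int64)
        return LabelMask(labels)
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr.astype(np.int64), bit_depth=bit_depth)


def write_png(obj, path, *, scale_mask: bool = True) -> None:
    """Write a :class:`GrayImage` or binary :class:`LabelMask` to PNG.

    Images round-trip bit-exactly through :func:`read_png`. Binary masks are
    scaled to {0, 255} on disk when ``scale_mask`` is true (the default).
    Out-of-range values are rejected, never clipped.
    """
    path = Path(path)
    if isinstance(obj, LabelMask):
        if obj.n_classes > 2 and scale_mask:
            raise ValueError("mask scaling to {0,255} requires a binary mask")
        arr = obj.labels
        out = (arr * 255 if scale_mask else arr).astype(np.uint8)
    elif isinstance(obj, GrayImage):
        arr = obj.values
        if arr.max(initial=0) > obj.max_value or arr.min(initial=0) < 0:
            raise ValueError("values exceed declared bit depth")
        out = arr.astype(np.uint8 if obj.bit_depth == 8 else np.uint16)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    iio.imwrite(path, out)


def map_12bit_to_8bit(image: GrayImage, *, stretch: bool = False) -> GrayImage:
    """Map a 12-bit image to 8 bits.

    The default mapping is the fixed divide ``v8 = floor(v12 / 16)``, which is
    deterministic across images. ``stretch=True`` instead applies a per-image
    min-max stretch onto [0, 255] (rounding half-up), which equalises
    exposure differences at the cost of image-dependent scaling.
    """
    if image.bit_depth != 12:
        raise ValueError(
            f"expected a 12-bit image, got bit depth {image.bit_depth}; "
            "an 8-bit image needs no mapping"
        )
    v = image.values.astype(np.float64)
    if stretch:
        lo, hi = v.min(), v.max()
        out = np.zeros_like(v) if hi == lo else (v - lo) * (255.0 / (hi - lo))
        out = np.floor(out + 0.5)
    else:
        out = np.floor(v / 16.0)
    return GrayImage(out.astype(np.int64), bit_depth=8)
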