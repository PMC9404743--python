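"""Chest-like phantom generation with ground truth.

A phantom emulates the intensity structure that drives lung field
segmentation in a radiograph: two dark elliptical "lung" regions on a bright
"body" background, optionally a dark distractor blob outside the lungs
(mimicking stomach gas, which naive intensity segmentation picks up) and a
bright lesion blob inside a lung (which punches a hole into the naive
segmentation). Ground truth is the union of the two lung ellipses only: the
distractor is excluded, the lesion area counts as lung.

Additive Gaussian noise and small random rotations (the augmentation used
when training segmenters) are available. Everything is deterministic under a
seed.

The phantoms are deliberately simple: no ribs, clavicles, mediastinum
texture or exposure gradients. They exercise the geometry and intensity
contrasts the pipeline depends on, not radiographic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_model import GrayImage, LabelMask

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "ellipse_mask",
    "make_phantom",
    "augment_rotate",
    "make_dataset",
    "default_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis specification: center (row, col), semi-axes (row, col), and a
    counter-clockwise rotation in degrees."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle_deg: float = 0.0


def ellipse_mask(shape: tuple[int, int], ell: Ellipse) -> np.ndarray:
    """Boolean rasterization: pixel centers inside or on the ellipse."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy = rr - ell.center[0]
    dx = cc - ell.center[1]
    th = np.deg2rad(ell.angle_deg)
    u = dy * np.cos(th) + dx * np.sin(th)
    v = -dy * np.sin(th) + dx * np.cos(th)
    a, b = ell.axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom.

    Intensities are 8-bit graylevels. The defaults give a lung/body contrast
    of 140 graylevels, far above any noise level the generator defaults to,
    so noise-free phantoms are exactly separable by a midpoint threshold.
    """

    width: int = 256
    height: int = 256
    lungs: tuple[Ellipse, Ellipse] = (
        Ellipse(center=(118.0, 72.0), axes=(80.0, 42.0), angle_deg=-4.0),
        Ellipse(center=(118.0, 184.0), axes=(80.0, 42.0), angle_deg=4.0),
    )
    lung_intensity: int = 40
    body_intensity: int = 180
    border_air_intensity: int | None = None  # None -> body intensity
    distractor: Ellipse | None = None  # dark blob outside the lungs
    lesion: Ellipse | None = None  # bright blob inside a lung
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        shape = (self.height, self.width)
        m0 = ellipse_mask(shape, self.lungs[0])
        m1 = ellipse_mask(shape, self.lungs[1])
        for name, m, e in (("left lung", m0, self.lungs[0]),
                           ("right lung", m1, self.lungs[1])):
            if not m.any():
                raise ValueError(f"{name} rasterizes to nothing")
            inside = ellipse_mask((self.height + 2, self.width + 2),
                                  Ellipse((e.center[0] + 1, e.center[1] + 1),
                                          e.axes, e.angle_deg))
            if inside[0, :].any() or inside[-1, :].any() \
                    or inside[:, 0].any() or inside[:, -1].any():
                raise ValueError(f"{name} extends beyond the image")
        if (m0 & m1).any():
            raise ValueError("lung ellipses overlap")
        if self.distractor is not None:
            d = ellipse_mask(shape, self.distractor)
            if (d & (m0 | m1)).any():
                raise ValueError("distractor intersects a lung")
        if self.lesion is not None:
            les = ellipse_mask(shape, self.lesion)
            if not (les <= (m0 | m1)).all():
                raise ValueError("lesion must lie entirely inside a lung")


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, LabelMask]:
    """Render a phantom image and its ground-truth lung mask."""
    spec.validate()
    shape = (spec.height, spec.width)
    lungs = ellipse_mask(shape, spec.lungs[0]) | ellipse_mask(shape, spec.lungs[1])
    img = np.full(shape, float(spec.body_intensity))
    img[lungs] = spec.lung_intensity
    if spec.distractor is not None:
        img[ellipse_mask(shape, spec.distractor)] = spec.lung_intensity
    if spec.lesion is not None:
        img[ellipse_mask(shape, spec.lesion)] = spec.body_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.int64)
    return GrayImage(img, bit_depth=8), LabelMask(lungs.astype(np.int64))


def augment_rotate(image: GrayImage, mask: LabelMask, max_deg: float,
                   seed: int | None = None, *, angle: float | None = None,
                   fill_value: int = 0) -> tuple[GrayImage, LabelMask]:
    """Rotate an image/mask pair by a random angle in [-max_deg, +max_deg].

    The image is resampled bilinearly, the mask with nearest-neighbor so
    labels stay binary. The canvas size is preserved; exposed corners take
    ``fill_value`` in the image and background in the mask. Pass ``angle``
    explicitly to bypass the draw.
    """
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    if angle is None:
        rng = np.random.default_rng(seed)
        angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0:
        return image, mask
    img = ndimage.rotate(image.values.astype(np.float64), angle, reshape=False,
                         order=1, mode="constant", cval=float(fill_value))
    img = np.clip(np.floor(img + 0.5), 0, image.max_value).astype(np.int64)
    lab = ndimage.rotate(mask.labels, angle, reshape=False, order=0,
                         mode="constant", cval=0)
    return GrayImage(img, bit_depth=image.bit_depth), LabelMask(lab, mask.n_classes)


def default_spec(size: int = 256, seed: int = 0, *, noise_sigma: float = 0.0,
                 with_distractor: bool = False, with_lesion: bool = False,
                 rng: np.random.Generator | None = None) -> PhantomSpec:
    """A randomly jittered phantom at the standard geometry.

    Lung centers, semi-axes and tilt are drawn from narrow uniform ranges
    around the canonical layout so that datasets show realistic anatomical
    variation while keeping the invariants (lungs inside the frame,
    non-overlapping) satisfied by construction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s = size / 256.0

    def jit(lo, hi):
        return float(rng.uniform(lo, hi))

    lungs = []
    for side, cx in ((-1, 72.0), (+1, 184.0)):
        lungs.append(Ellipse(
            center=((118.0 + jit(-6, 6)) * s, (cx + side * jit(-4, 4)) * s),
            axes=((80.0 + jit(-8, 8)) * s, (42.0 + jit(-5, 5)) * s),
            angle_deg=side * jit(2, 6),
        ))
    distractor = lesion = None
    if with_distractor:
        distractor = Ellipse(center=(225.0 * s, (128.0 + jit(-10, 10)) * s),
                             axes=(14.0 * s, 20.0 * s), angle_deg=jit(-20, 20))
    if with_lesion:
        host = lungs[0]
        lesion = Ellipse(center=(host.center[0] + jit(-8, 8) * s,
                                 host.center[1] + jit(-4, 4) * s),
                         axes=(9.0 * s, 7.0 * s), angle_deg=jit(-30, 30))
    return PhantomSpec(width=size, height=size, lungs=tuple(lungs),
                       distractor=distractor, lesion=lesion,
                       noise_sigma=noise_sigma, seed=int(rng.integers(2**31)))


def make_dataset(n: int, *, size: int = 256, noise_sigma: float = 0.0,
                 with_distractor: bool = False, with_lesion: bool = False,
                 seed: int = 0, out_dir=None):
    """Generate ``n`` phantoms, reproducibly from ``seed``.

    Returns a list of ``(GrayImage, LabelMask)``. With ``out_dir`` the pairs
    are also written as PNG files alongside a JSON manifest of the specs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pairs, specs = [], []
    for _ in range(n):
        spec = default_spec(size=size, noise_sigma=noise_sigma,
                            with_distractor=with_distractor,
                            with_lesion=with_lesion, rng=rng)
        pairs.append(make_phantom(spec))
        specs.append(spec)
    if out_dir is not None:
        from .image_model import write_png

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, ((img, mask), spec) in enumerate(zip(pairs, specs)):
            img_name, mask_name = f"phantom_{i:03d}.png", f"phantom_{i:03d}_mask.png"
            write_png(img, out_dir / img_name)
            write_png(mask, out_dir / mask_name)
            manifest.append({"image": img_name, "mask": mask_name,
                             "spec": asdict(spec)})
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return pairs
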