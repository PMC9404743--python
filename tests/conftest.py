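import numpy as np
import pytest

from lungseg.image_model import GrayImage
from lungseg.synthetic import default_spec, make_phantom


def stripe_image(rng: np.random.Generator, size: int = 64,
                 horizontal: bool = False) -> np.ndarray:
    """Piecewise-constant stripes with edges at multiples of 8 offset by
    +/-1 px, alternating dark/bright bands (contrast >= 120). Such edges
    align with USEQ superpixel boundaries at rates 0.5 / 0.25 / 0.125 but
    defeat plain block-aligned resampling."""
    edges = [0]
    for k in range(8, size, 8):
        edges.append(k + int(rng.choice([-1, 1])))
    edges.append(size)
    vals = np.empty(size, dtype=np.int64)
    dark_first = int(rng.integers(0, 2))
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        lo, hi = ((20, 60) if (i + dark_first) % 2 == 0 else (180, 240))
        vals[a:b] = rng.integers(lo, hi + 1)
    img = np.tile(vals, (size, 1))
    return img.T if horizontal else img


def random_mask(rng: np.random.Generator, shape=(16, 16),
                p: float = 0.5, nonempty: bool = False) -> np.ndarray:
    m = (rng.random(shape) < p).astype(np.int64)
    if nonempty and m.sum() == 0:
        m[tuple(rng.integers(0, s) for s in shape)] = 1
    return m


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic noise-free 256x256 phantom with ground truth."""
    return make_phantom(default_spec(size=256, seed=42))


@pytest.fixture(scope="session")
def artifact_phantom():
    """Phantom with a dark distractor outside the lungs and a bright lesion
    inside one lung, as naive intensity segmentation stumbles over."""
    return make_phantom(default_spec(size=256, seed=7, with_distractor=True,
                                     with_lesion=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
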