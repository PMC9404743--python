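"""Low-resolution segmenters.

Two interchangeable segmenters operate on the downsampled image:

* :class:`ThresholdSegmenter` — a deterministic reference that labels every
  pixel darker than a threshold as lung. It exploits the fact that the
  air-filled lung fields are the darkest large structures in a radiograph,
  and serves as a fast, training-free baseline for pipeline experiments.

* :class:`EncoderDecoderSegmenter` — a compact SegNet-style convolutional
  encoder–decoder written in numpy. Each encoder stage is conv(3x3) → batch
  norm → ReLU → 2x2 max pool; the pool records the argmax location in each
  window and the mirrored decoder stage uses those pooling indices for sparse
  upsampling (unpool → conv → batch norm → ReLU), ending in a per-pixel
  softmax over the classes. Training minimises per-pixel cross-entropy with
  Adam and is fully deterministic given a seed.

The full-scale profile of the architecture (five stages, 256x256 inputs,
40,000 iterations, lr 5e-4, batch 4) is reachable through the parameters;
the tested surface is the toy profile (three stages, channels (8, 16, 32),
64x64 inputs, a few hundred iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from .image_model import GrayImage, LabelMask
from .useq import _as_values

__all__ = [
    "threshold_segment",
    "pool_with_indices",
    "unpool_with_indices",
    "build_encoder_decoder",
    "train",
    "predict",
    "ThresholdSegmenter",
    "EncoderDecoderSegmenter",
    "PretrainedSegmenter",
    "save_checkpoint",
    "load_checkpoint",
    "segmenter_from_config",
]


def threshold_segment(image, t: float) -> LabelMask:
    """Label pixels darker than ``t`` as lung (1), the rest background (0)."""
    vals = _as_values(image)
    return LabelMask((vals < t).astype(np.int64))


# -- pooling primitives ------------------------------------------------------

def pool_with_indices(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling with stride 2, returning values and argmax locations.

    ``features`` may have any leading dimensions; the last two must be even.
    Indices are the flat position (0..3, row-major) of the maximum within
    each window; ties take the first position in row-major order.
    """
    x = np.asarray(features)
    *lead, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"side lengths must be even, got {H}x{W}")
    win = x.reshape(*lead, H // 2, 2, W // 2, 2)
    win = np.moveaxis(win, -3, -2).reshape(*lead, H // 2, W // 2, 4)
    idx = np.argmax(win, axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def unpool_with_indices(pooled: np.ndarray, indices: np.ndarray,
                        out_shape: tuple[int, int]) -> np.ndarray:
    """Place pooled values back at their stored window locations, zeros
    elsewhere. Inverse of the value-routing of :func:`pool_with_indices`."""
    p = np.asarray(pooled)
    idx = np.asarray(indices)
    if p.shape != idx.shape:
        raise ValueError("pooled and indices shapes differ")
    H, W = out_shape
    *lead, h2, w2 = p.shape
    if (h2 * 2, w2 * 2) != (H, W):
        raise ValueError(f"out_shape {out_shape} incompatible with pooled {p.shape}")
    win = np.zeros((*lead, h2, w2, 4), dtype=p.dtype)
    np.put_along_axis(win, idx[..., None], p[..., None], axis=-1)
    win = win.reshape(*lead, h2, w2, 2, 2)
    return np.moveaxis(win, -2, -3).reshape(*lead, H, W)


# -- layers ------------------------------------------------------------------

class _Conv3x3:
    """Same-padded 3x3 convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 9
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)),
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * W, C * 9)
        self._cols, self._in_shape = cols, (N, C, H, W)
        out = cols @ self.params["W"].T + self.params["b"]
        return out.transpose(0, 2, 1).reshape(N, self.out_ch, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        d = dout.reshape(N, self.out_ch, H * W).transpose(0, 2, 1)  # (N,HW,out)
        self.grads["W"][:] = np.einsum("nko,nki->oi", d, self._cols)
        self.grads["b"][:] = d.sum(axis=(0, 1))
        dcols = d @ self.params["W"]  # (N, HW, C*9)
        dcols = dcols.reshape(N, H, W, C, 3, 3)
        dxp = np.zeros((N, C, H + 2, W + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class _BatchNorm:
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(ch), "beta": np.zeros(ch)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._std = np.sqrt(v + self.eps)
        return self.params["gamma"][None, :, None, None] * self._xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"][:] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][:] = dout.sum(axis=(0, 2, 3))
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx / self._std


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


@dataclass
class _EncoderStage:
    conv: _Conv3x3
    bn: _BatchNorm
    relu: _ReLU


@dataclass
class _DecoderStage:
    conv: _Conv3x3
    bn: _BatchNorm
    relu: _ReLU


class EncoderDecoderNet:
    """SegNet-style encoder–decoder with pooling-index unpooling.

    Inputs are (N, 1, H, W) graylevel rasters scaled to [0, 1]; H and W must
    be divisible by ``2**n_stages``. Output is (N, n_classes, H, W) softmax
    probabilities.
    """

    def __init__(self, n_stages: int = 3, channels=(8, 16, 32),
                 n_classes: int = 2, seed: int = 0):
        if len(channels) < n_stages:
            raise ValueError("need one channel width per stage")
        channels = tuple(channels[:n_stages])
        rng = np.random.default_rng(seed)
        self.n_stages = n_stages
        self.channels = channels
        self.n_classes = n_classes
        self.encoder = []
        in_ch = 1
        for ch in channels:
            self.encoder.append(_EncoderStage(_Conv3x3(in_ch, ch, rng),
                                              _BatchNorm(ch), _ReLU()))
            in_ch = ch
        self.decoder = []
        dec_out = list(channels[-2::-1]) + [channels[0]]
        for out_ch in dec_out:
            self.decoder.append(_DecoderStage(_Conv3x3(in_ch, out_ch, rng),
                                              _BatchNorm(out_ch), _ReLU()))
            in_ch = out_ch
        self.classifier = _Conv3x3(in_ch, n_classes, rng)

    # parameter plumbing -----------------------------------------------------
    def _layers(self):
        for st in self.encoder:
            yield st.conv
            yield st.bn
        for st in self.decoder:
            yield st.conv
            yield st.bn
        yield self.classifier

    def parameters(self):
        return [(layer, name) for layer in self._layers() for name in layer.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Softmax class probabilities for a (N, 1, H, W) batch in [0, 1]."""
        if x.ndim != 4:
            raise ValueError("expected a (N, 1, H, W) batch")
        H, W = x.shape[2:]
        div = 1 << self.n_stages
        if H % div or W % div:
            raise ValueError(f"input sides must be divisible by {div}")
        self._pool_indices, self._pool_shapes = [], []
        for st in self.encoder:
            x = st.relu.forward(st.bn.forward(st.conv.forward(x, train), train), train)
            self._pool_shapes.append(x.shape[2:])
            x, idx = pool_with_indices(x)
            self._pool_indices.append(idx)
        for st, idx, shape in zip(self.decoder, self._pool_indices[::-1],
                                  self._pool_shapes[::-1]):
            x = unpool_with_indices(x, idx, shape)
            x = st.relu.forward(st.bn.forward(st.conv.forward(x, train), train), train)
        logits = self.classifier.forward(x, train)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, y: np.ndarray) -> None:
        """Backpropagate the cross-entropy gradient for integer targets
        ``y`` of shape (N, H, W); call after a training-mode forward."""
        probs = self._probs
        N, K, H, W = probs.shape
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, y[:, None, :, :], 1.0, axis=1)
        d = (probs - onehot) / (N * H * W)
        d = self.classifier.backward(d)
        for st, idx in zip(self.decoder[::-1], self._pool_indices):
            d = st.conv.backward(st.bn.backward(st.relu.backward(d)))
            # gradient of unpool: gather from the scattered positions
            d, _ = _gather_unpool_grad(d, idx)
        for st in self.encoder[::-1]:
            # gradient of pool: scatter to the argmax positions
            d = unpool_with_indices(d, self._pool_indices_for(st), self._shape_for(st))
            d = st.conv.backward(st.bn.backward(st.relu.backward(d)))

    # helpers used by backward (set up during forward)
    def _pool_indices_for(self, st):
        return self._pool_indices[self.encoder.index(st)]

    def _shape_for(self, st):
        return self._pool_shapes[self.encoder.index(st)]

    def loss(self, y: np.ndarray) -> float:
        """Mean per-pixel cross-entropy of the last forward pass."""
        probs = self._probs
        p = np.take_along_axis(probs, y[:, None, :, :], axis=1)[:, 0]
        return float(-np.log(np.maximum(p, 1e-12)).mean())


def _gather_unpool_grad(dout: np.ndarray, idx: np.ndarray):
    """Gradient of unpool_with_indices w.r.t. its pooled input: pick the
    gradient at each stored location."""
    *lead, H, W = dout.shape
    win = dout.reshape(*lead, H // 2, 2, W // 2, 2)
    win = np.moveaxis(win, -3, -2).reshape(*lead, H // 2, W // 2, 4)
    return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], None


class _Adam:
    def __init__(self, net: EncoderDecoderNet, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net._layers()}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net._layers()}

    def step(self, net: EncoderDecoderNet) -> None:
        self.t += 1
        for layer in net._layers():
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[id(layer)][k]
                v = self.v[id(layer)][k]
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_encoder_decoder(n_stages: int = 3, channels=(8, 16, 32),
                          n_classes: int = 2, seed: int = 0) -> EncoderDecoderNet:
    """Seeded construction of the encoder–decoder network."""
    return EncoderDecoderNet(n_stages=n_stages, channels=channels,
                             n_classes=n_classes, seed=seed)


def _to_batch(images) -> np.ndarray:
    arrs = [_as_values(im).astype(np.float64) / 255.0 for im in images]
    return np.stack(arrs)[:, None, :, :]


def train(net: EncoderDecoderNet, images, masks, *, lr: float = 5e-4,
          batch_size: int = 4, max_iter: int = 500, seed: int = 0):
    """Minimise per-pixel cross-entropy with Adam.

    ``images`` and ``masks`` are matching sequences of 2-D rasters. Batches
    are drawn with a generator seeded by ``seed``; the whole run is
    deterministic. Returns the network with ``loss_curve`` attached. A
    non-finite loss aborts with a diagnostic.
    """
    X = _to_batch(images)
    y = np.stack([(m.labels if isinstance(m, LabelMask) else np.asarray(m))
                  for m in masks]).astype(np.int64)
    if X.shape[0] != y.shape[0] or X.shape[2:] != y.shape[1:]:
        raise ValueError("images and masks must match in count and shape")
    if X.shape[0] < 1:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(seed)
    opt = _Adam(net, lr)
    curve = []
    for it in range(max_iter):
        sel = rng.choice(X.shape[0], size=min(batch_size, X.shape[0]), replace=False)
        net.forward(X[sel], train=True)
        loss = net.loss(y[sel])
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}: {loss}")
        curve.append(loss)
        net.backward(y[sel])
        opt.step(net)
    net.loss_curve = curve
    return net


def predict(net: EncoderDecoderNet, image) -> LabelMask:
    """Per-pixel argmax of class probabilities (ties to the lower class).

    Inputs whose sides are not divisible by ``2**n_stages`` are reflect-
    padded up and the prediction is cropped back.
    """
    vals = _as_values(image)
    H, W = vals.shape
    div = 1 << net.n_stages
    ph = (-H) % div
    pw = (-W) % div
    padded = np.pad(vals, ((0, ph), (0, pw)), mode="reflect") if ph or pw else vals
    probs = net.forward(_to_batch([padded]), train=False)[0]
    labels = np.argmax(probs, axis=0)[:H, :W]
    return LabelMask(labels.astype(np.int64), n_classes=net.n_classes)


# -- estimators --------------------------------------------------------------

class ThresholdSegmenter(ClassifierMixin, BaseEstimator):
    """Training-free intensity-threshold segmenter (lung = darker than t)."""

    def __init__(self, threshold: float = 110.0):
        self.threshold = threshold

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict(self, image) -> LabelMask:
        return threshold_segment(image, self.threshold)


class EncoderDecoderSegmenter(ClassifierMixin, BaseEstimator):
    """The numpy encoder–decoder as a fit/predict estimator.

    Parameters mirror the training configuration; ``fit`` expects matching
    sequences of 2-D images and masks whose sides are divisible by
    ``2**n_stages``. The fitted network is in ``net_`` and the training loss
    trajectory in ``loss_curve_``.
    """

    def __init__(self, n_stages: int = 3, channels=(8, 16, 32),
                 n_classes: int = 2, lr: float = 5e-3, batch_size: int = 4,
                 max_iter: int = 500, seed: int = 0):
        self.n_stages = n_stages
        self.channels = channels
        self.n_classes = n_classes
        self.lr = lr
        self.batch_size = batch_size
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        net = build_encoder_decoder(self.n_stages, self.channels,
                                    self.n_classes, self.seed)
        train(net, X, y, lr=self.lr, batch_size=self.batch_size,
              max_iter=self.max_iter, seed=self.seed)
        self.net_ = net
        self.loss_curve_ = net.loss_curve
        return self

    def predict(self, image) -> LabelMask:
        return predict(self.net_, image)


def save_checkpoint(net: EncoderDecoderNet, path) -> None:
    """Serialize network parameters, batch-norm statistics and the
    architecture configuration to a single ``.npz`` file."""
    import json

    arrays = {"config": np.array(json.dumps({
        "n_stages": net.n_stages, "channels": list(net.channels),
        "n_classes": net.n_classes}))}
    for i, layer in enumerate(net._layers()):
        for k, v in layer.params.items():
            arrays[f"l{i}_{k}"] = v
        if isinstance(layer, _BatchNorm):
            arrays[f"l{i}_running_mean"] = layer.running_mean
            arrays[f"l{i}_running_var"] = layer.running_var
    np.savez(path, **arrays)


def load_checkpoint(path) -> EncoderDecoderNet:
    """Rebuild a network from :func:`save_checkpoint` output."""
    import json

    data = np.load(path)
    cfg = json.loads(str(data["config"]))
    net = EncoderDecoderNet(n_stages=cfg["n_stages"],
                            channels=tuple(cfg["channels"]),
                            n_classes=cfg["n_classes"], seed=0)
    for i, layer in enumerate(net._layers()):
        for k in layer.params:
            layer.params[k][:] = data[f"l{i}_{k}"]
        if isinstance(layer, _BatchNorm):
            layer.running_mean[:] = data[f"l{i}_running_mean"]
            layer.running_var[:] = data[f"l{i}_running_var"]
    return net


class PretrainedSegmenter:
    """Prediction-only wrapper around a loaded checkpoint."""

    def __init__(self, net: EncoderDecoderNet):
        self.net_ = net

    def fit(self, X=None, y=None):
        return self

    def predict(self, image) -> LabelMask:
        return predict(self.net_, image)


def segmenter_from_config(cfg: dict):
    """Build a segmenter estimator from a plain configuration mapping.

    ``{"kind": "threshold", "threshold": 110}`` or
    ``{"kind": "encoder_decoder", "n_stages": 3, ...}``.
    """
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    if kind == "threshold":
        return ThresholdSegmenter(**cfg)
    if kind == "encoder_decoder":
        return EncoderDecoderSegmenter(**cfg)
    raise ValueError(f"unknown segmenter kind {kind!r}")
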