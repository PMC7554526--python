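"""2D U-net segmentation model, training regime and sklearn-style estimator.

The network follows the classic U-net layout: a contracting path of
double 3x3 convolution blocks with 2x2 max pooling, an expanding path of
nearest-neighbour upsampling plus convolution, and skip connections that
concatenate encoder features at each resolution level. Same-padding is
used throughout so the output probability map has the input's spatial
shape, and the final 1x1 convolution is squashed through a sigmoid so
every pixel carries a lesion probability in [0, 1].

Training uses stochastic gradient descent on mean pixel-wise cross
entropy (initial learning rate 0.01, batch size 4 by default), with
augmentation resampled per slice in every epoch when an augmenter is
supplied. Depth and base filter count are configurable so the same code
runs both at publication scale (depth 4, 64 filters) and at a desk scale
that trains on one CPU in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .errors import ConfigurationError, DivergenceError, GeometryError, NoDataError

logger = logging.getLogger(__name__)

__all__ = [
    "NetConfig",
    "TrainConfig",
    "UNet",
    "build_network",
    "train",
    "predict",
    "UNetSegmenter",
]


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    in_channels is 1 for single-modality input (FLAIR, or DWI for the
    acute-lesion network) and 2 for the stacked FLAIR+DWI input.
    """

    in_channels: int = 1
    depth: int = 2
    base_filters: int = 8
    # preprocessed volumes arrive on the [0, 255] scale; the network
    # rescales them to [0, 1] so He-initialised weights are well posed
    input_scale: float = 1.0 / 255.0

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ConfigurationError(f"in_channels must be 1 or 2, got {self.in_channels}")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")


@dataclass
class TrainConfig:
    """Optimisation regime: SGD on pixel-wise cross entropy."""

    learning_rate: float = 0.01
    batch_size: int = 4
    epochs: int = 100
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


class _DoubleConv:
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = _nn.Conv2d(in_ch, out_ch, 3, rng)
        self.r1 = _nn.ReLU()
        self.c2 = _nn.Conv2d(out_ch, out_ch, 3, rng)
        self.r2 = _nn.ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x, train=True):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train), train)

    def backward(self, g):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(g))))


class UNet:
    """Symmetric encoder--decoder with skip connections (NumPy, CPU)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = [cfg.base_filters * 2**d for d in range(cfg.depth + 1)]
        self.enc = []
        prev = cfg.in_channels
        for d in range(cfg.depth):
            self.enc.append(_DoubleConv(prev, ch[d], rng))
            prev = ch[d]
        self.pools = [_nn.MaxPool2() for _ in range(cfg.depth)]
        self.bottleneck = _DoubleConv(prev, ch[cfg.depth], rng)
        self.ups = [_nn.Upsample2() for _ in range(cfg.depth)]
        self.upconv = []
        self.dec = []
        prev = ch[cfg.depth]
        for d in reversed(range(cfg.depth)):
            self.upconv.append(_nn.Conv2d(prev, ch[d], 3, rng))
            self.dec.append(_DoubleConv(2 * ch[d], ch[d], rng))
            prev = ch[d]
        self.head = _nn.Conv2d(prev, 1, 1, rng)

    @property
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params
        out += self.bottleneck.params
        for c, blk in zip(self.upconv, self.dec):
            out += c.params + blk.params
        out += self.head.params
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    def _check_side(self, h: int, w: int) -> None:
        f = 2**self.cfg.depth
        if h % f or w % f:
            raise GeometryError(
                f"input side ({h}x{w}) must be divisible by 2^depth = {f}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        self._check_side(x.shape[2], x.shape[3])
        x = x.astype(np.float32, copy=False) * np.float32(self.cfg.input_scale)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for up, conv, blk, skip in zip(self.ups, self.upconv, self.dec, reversed(skips)):
            x = conv.forward(up.forward(x, train), train)
            self._skip_ch.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1), train)
        return self.head.forward(x, train)[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad[:, None])
        skip_grads = []
        for conv, blk, up, sc in zip(
            reversed(self.upconv), reversed(self.dec), reversed(self.ups), reversed(self._skip_ch)
        ):
            g = blk.backward(g)
            skip_grads.append(g[:, :sc])
            g = up.backward(conv.backward(g[:, sc:]))
        g = self.bottleneck.backward(g)
        # skip_grads collected shallowest-level-first; encoder runs deepest-first
        for blk, pool, sg in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g) + sg
            g = blk.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.forward_logits(x, train=False))


def build_network(cfg: NetConfig, seed: int = 0) -> UNet:
    """Instantiate a U-net with deterministic, seeded initialisation."""
    return UNet(cfg, seed=seed)


def train(
    network: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    tcfg: TrainConfig,
    augmenter=None,
) -> list[float]:
    """Train in place; returns per-epoch mean cross-entropy history.

    images: (n_slices, C, H, W) float; masks: (n_slices, H, W) binary.
    The augmenter, when given, is called as augmenter(image, mask) for
    every slice in every epoch, drawing fresh transform parameters.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    if images.shape[0] == 0:
        raise NoDataError("empty training set")
    if images.shape[0] != masks.shape[0]:
        raise NoDataError("images and masks differ in slice count")
    opt = _nn.SGD(network.params, lr=tcfg.learning_rate, momentum=tcfg.momentum)
    rng = np.random.default_rng(tcfg.seed)
    n = images.shape[0]
    history: list[float] = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = images[idx], masks[idx]
            if augmenter is not None:
                xb = xb.copy()
                yb = yb.copy()
                for i in range(len(idx)):
                    xb[i], yb[i] = augmenter(xb[i], yb[i])
            logits = network.forward_logits(xb, train=True)
            loss, grad = _nn.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.zero_grad()
            network.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.debug("epoch %d: loss %.5f", epoch, history[-1])
    return history


def predict(network: UNet, volume: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Slice-wise inference on a (S, C, H, W) or (S, H, W) stack.

    Returns per-voxel probabilities in [0, 1], stacked in slice order.
    Deterministic: no augmentation or dropout at inference.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim == 3:
        volume = volume[:, None]
    if volume.shape[1] != network.cfg.in_channels:
        raise ConfigurationError(
            f"volume has {volume.shape[1]} channels, network expects {network.cfg.in_channels}"
        )
    out = [network.predict_proba(volume[i : i + batch_size]) for i in range(0, len(volume), batch_size)]
    return np.concatenate(out, axis=0) if out else np.zeros((0,) + volume.shape[2:], np.float32)


class UNetSegmenter(BaseEstimator):
    """Sklearn-style wrapper: fit on (n, C, H, W) slices, predict masks.

    Parameters mirror NetConfig and TrainConfig; fitted state lives in
    ``net_`` and ``loss_history_``.
    """

    def __init__(
        self,
        in_channels: int = 1,
        depth: int = 2,
        base_filters: int = 8,
        learning_rate: float = 0.01,
        batch_size: int = 4,
        epochs: int = 100,
        momentum: float = 0.9,
        seed: int = 0,
        augmenter=None,
    ):
        self.in_channels = in_channels
        self.depth = depth
        self.base_filters = base_filters
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.momentum = momentum
        self.seed = seed
        self.augmenter = augmenter

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        cfg = NetConfig(self.in_channels, self.depth, self.base_filters)
        tcfg = TrainConfig(self.learning_rate, self.batch_size, self.epochs, self.momentum, self.seed)
        self.net_ = build_network(cfg, seed=self.seed)
        self.loss_history_ = train(self.net_, X, np.asarray(y), tcfg, augmenter=self.augmenter)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return predict(self.net_, np.asarray(X, dtype=np.float32))

    def predict(self, X, tau: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) > tau
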