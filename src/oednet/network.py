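"""The configurable CNN: dilated convolution blocks, batch normalization,
ReLU, 2x2 max pooling, global pooling variants, and a fully connected head.

Every convolution is a *valid* (unpadded) cross-correlation -- kernels are
not flipped -- so a 3x3 kernel shrinks each spatial side by 2, and an
l-dilated w x w kernel by (w-1)*l while keeping w*w free weights.  A
convolution block is

    [l1-dilated w1 conv, BN, ReLU][l2-dilated w2 conv, BN, ReLU][2x2 max pool]

and the head is global pooling (GAP / GMP / GLSEP) -> dense hidden layer
with ReLU and dropout -> 3-way output, softmax at inference.

Layers carry their own backward passes (the package trains without a
deep-learning framework); the im2col-based convolution is independently
checked against :func:`atrous_convolve_reference`, a direct loop evaluation
of the dilated-convolution sum.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

LABELS = ("others", "irregular_stratification", "bulbous_rete_ridge")
GLOBAL_POOL_VARIANTS = ("GAP", "GMP", "GLSEP")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConvBlockConfig:
    """One conv block: dilated w1 conv then pointwise-style w2 conv.

    ``l1``/``l2`` are dilation factors, ``w1``/``w2`` odd kernel sides.
    """

    out_channels: int
    l1: int = 1
    l2: int = 1
    w1: int = 3
    w2: int = 1
    use_bn: bool = True

    def __post_init__(self) -> None:
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        for name in ("l1", "l2"):
            if getattr(self, name) < 1:
                raise ValueError(f"dilation {name} must be >= 1")
        for name in ("w1", "w2"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"kernel side {name} must be odd and >= 1")


@dataclasses.dataclass(frozen=True)
class ArchitectureConfig:
    """Full hyperparameter tuple spanning the ablation design space."""

    blocks: tuple[ConvBlockConfig, ...]
    global_pool: str = "GAP"
    hidden_width: int = 2048
    dropout_rate: float = 0.0
    input_side: int = 350
    num_classes: int = 3
    color_space: str = "YCbCr"

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.global_pool not in GLOBAL_POOL_VARIANTS:
            raise ValueError(f"global_pool must be one of {GLOBAL_POOL_VARIANTS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.color_space not in ("YCbCr", "RGB"):
            raise ValueError("color_space must be 'YCbCr' or 'RGB'")
        if self.num_classes != 3:
            raise ValueError("the classifier has exactly 3 output classes")

    @property
    def feature_channels(self) -> int:
        """M, the channel count entering global pooling."""
        return self.blocks[-1].out_channels if self.blocks else 3

    def to_dict(self) -> dict:
        return {
            "blocks": [dataclasses.asdict(b) for b in self.blocks],
            "global_pool": self.global_pool,
            "hidden_width": self.hidden_width,
            "dropout_rate": self.dropout_rate,
            "input_side": self.input_side,
            "num_classes": self.num_classes,
            "color_space": self.color_space,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        blocks = tuple(ConvBlockConfig(**b) for b in d["blocks"])
        rest = {k: v for k, v in d.items() if k != "blocks"}
        return cls(blocks=blocks, **rest)


def make_architecture(
    channels: Sequence[int] = (16, 32, 64, 128, 256),
    l1: int = 1,
    l2: int = 1,
    w1: int = 3,
    w2: int = 1,
    bn: bool = True,
    pool: str = "GAP",
    h1: int = 2048,
    p: float = 0.0,
    color_space: str = "YCbCr",
    input_side: int = 350,
) -> ArchitectureConfig:
    """Build a config in the ablation table's row vocabulary: every block
    shares (l1, l2, w1, w2, bn) and the channel widths double per block."""
    blocks = tuple(
        ConvBlockConfig(out_channels=c, l1=l1, l2=l2, w1=w1, w2=w2, use_bn=bn)
        for c in channels
    )
    return ArchitectureConfig(
        blocks=blocks,
        global_pool=pool,
        hidden_width=h1,
        dropout_rate=p,
        color_space=color_space,
        input_side=input_side,
    )


#: The proposed architecture: five blocks with widths 16..256, all dilations 1,
#: 3x3 then 1x1 kernels, BN, GAP, hidden width 2048, no dropout; 1,014,867
#: trainable parameters on a 350x350 YCbCr input.
PROPOSED = make_architecture()


def ablation_table() -> list[tuple[int, ArchitectureConfig]]:
    """The 16 architecture variants of the ablation study, numbered 1-16."""
    rows = [
        dict(l1=1, l2=1, w1=3, w2=1, bn=False, pool="GAP", h1=1024, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=1024, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GMP", h1=1024, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GLSEP", h1=1024, p=0.0),
        dict(l1=2, l2=1, w1=3, w2=3, bn=True, pool="GAP", h1=1024, p=0.0),
        dict(l1=2, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=1024, p=0.0),
        dict(l1=2, l2=1, w1=3, w2=1, bn=False, pool="GAP", h1=1024, p=0.0),
        dict(l1=3, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=1024, p=0.0),
        dict(l1=3, l2=2, w1=3, w2=1, bn=True, pool="GAP", h1=1024, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=1024, p=0.5),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=512, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=2048, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=2048, p=0.5),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=2048, p=0.0,
             color_space="RGB"),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=4096, p=0.0),
        dict(l1=1, l2=1, w1=3, w2=1, bn=True, pool="GAP", h1=4096, p=0.5),
    ]
    return [(i + 1, make_architecture(**row)) for i, row in enumerate(rows)]


# ---------------------------------------------------------------------------
# Reference (oracle) operations
# ---------------------------------------------------------------------------

def atrous_convolve_reference(
    input: np.ndarray, kernel: np.ndarray, dilation: int
) -> np.ndarray:
    """Direct evaluation of the valid l-dilated cross-correlation.

    out[p] = sum_t input[p + l*t] * kernel[t] -- kernel taps spaced
    ``dilation`` pixels apart, no padding, no kernel flip.  The effective
    receptive field of a w x w kernel is ((w-1)*l + 1) per side, with only
    w*w free weights.  This is the brute-force oracle the framework layers
    are tested against; it is deliberately loop-based and independent of the
    im2col implementation.
    """
    x = np.asarray(input, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if x.ndim != 2 or k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("input must be 2-D and kernel square 2-D")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    w = k.shape[0]
    eff = (w - 1) * dilation + 1
    if x.shape[0] < eff or x.shape[1] < eff:
        raise ValueError(
            f"input of shape {x.shape} is smaller than the {eff}x{eff} "
            f"effective receptive field (kernel {w}, dilation {dilation})"
        )
    oh = x.shape[0] - (w - 1) * dilation
    ow = x.shape[1] - (w - 1) * dilation
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            acc = 0.0
            for s in range(w):
                for t in range(w):
                    acc += x[i + dilation * s, j + dilation * t] * k[s, t]
            out[i, j] = acc
    return out


def global_pool(maps: np.ndarray, variant: str) -> np.ndarray:
    """Reduce M feature maps of size F1 x F2 to an M-vector.

    GAP averages each map, GMP takes its maximum, GLSEP its log-sum-exp
    (computed max-shifted for stability).
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 3 or maps.shape[1] < 1 or maps.shape[2] < 1:
        raise ValueError("maps must be a non-empty (M, F1, F2) array")
    if variant == "GAP":
        return maps.mean(axis=(1, 2))
    if variant == "GMP":
        return maps.max(axis=(1, 2))
    if variant == "GLSEP":
        m = maps.max(axis=(1, 2), keepdims=True)
        return (m[:, 0, 0]
                + np.log(np.exp(maps - m).sum(axis=(1, 2))))
    raise ValueError(f"unknown global pooling variant {variant!r}")


# ---------------------------------------------------------------------------
# Trainable layers (NCHW float32 master weights; optional fp16 compute)
# ---------------------------------------------------------------------------

class Param:
    """A trainable tensor with its gradient accumulator (float32 master)."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    compute_dtype = np.float32

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class DilatedConv2d(Layer):
    """Valid l-dilated cross-correlation with bias, via im2col + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_side: int,
                 dilation: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = kernel_side
        self.l = dilation
        fan_in = in_channels * kernel_side * kernel_side
        self.weight = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel_side,
                             kernel_side))
        )
        self.bias = Param(np.zeros(out_channels))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _cols(self, x: np.ndarray) -> np.ndarray:
        n, c, h, wid = x.shape
        eff = (self.w - 1) * self.l + 1
        if h < eff or wid < eff:
            raise ValueError(
                f"spatial size {h}x{wid} below effective receptive field "
                f"{eff}x{eff}"
            )
        view = np.lib.stride_tricks.sliding_window_view(
            x, (eff, eff), axis=(2, 3)
        )[..., ::self.l, ::self.l]           # (N, C, oh, ow, w, w)
        oh, ow = view.shape[2], view.shape[3]
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(
            n * oh * ow, c * self.w * self.w
        )
        return np.ascontiguousarray(cols), oh, ow

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        dt = self.compute_dtype
        x = x.astype(dt, copy=False)
        cols, oh, ow = self._cols(x)
        wmat = self.weight.data.reshape(self.out_channels, -1).T.astype(dt)
        out = cols @ wmat + self.bias.data.astype(dt)
        self._cache = (cols, x.shape, oh, ow)
        return out.reshape(x.shape[0], oh, ow, self.out_channels) \
                  .transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape, oh, ow = self._cache
        dt = self.compute_dtype
        n = xshape[0]
        gm = grad.astype(dt, copy=False).transpose(0, 2, 3, 1).reshape(
            n * oh * ow, self.out_channels
        )
        dw = (cols.T @ gm).T.reshape(self.weight.data.shape)
        self.weight.grad += dw.astype(np.float32)
        self.bias.grad += gm.sum(axis=0).astype(np.float32)
        dx = np.zeros(xshape, dtype=dt)
        wk = self.weight.data.astype(dt)
        for s in range(self.w):
            for t in range(self.w):
                contrib = gm @ wk[:, :, s, t]       # (N*oh*ow, C_in)
                contrib = contrib.reshape(n, oh, ow, self.in_channels) \
                                 .transpose(0, 3, 1, 2)
                dx[:, :, s * self.l:s * self.l + oh,
                   t * self.l:t * self.l + ow] += contrib
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    Statistics are computed in float32 regardless of the compute dtype;
    running estimates (momentum 0.1) are used at inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _stats_dtype(self):
        # batch statistics never run at half precision
        return np.float32 if self.compute_dtype == np.float16 \
            else self.compute_dtype

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x32 = x.astype(self._stats_dtype(), copy=False)
        if training:
            mean = x32.mean(axis=(0, 2, 3))
            var = x32.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x32 - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        out = (self.gamma.data[None, :, None, None] * xhat
               + self.beta.data[None, :, None, None])
        return out.astype(self.compute_dtype, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = grad.astype(self._stats_dtype(), copy=False)
        axes = (0, 2, 3)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gy = g * self.gamma.data[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (
            m * gy
            - gy.sum(axis=axes, keepdims=True)
            - xhat * (gy * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(self.compute_dtype, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, :h2 * 2, :w2 * 2]
        windows = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5) \
                   .reshape(n, c, h2, w2, 4)
        self._argmax = windows.argmax(axis=-1)
        self._inshape = (n, c, h, w)
        return windows.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], grad[..., None],
                          axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class GlobalPool(Layer):
    """GAP / GMP / GLSEP over the spatial axes: (N, M, F1, F2) -> (N, M)."""

    def __init__(self, variant: str):
        if variant not in GLOBAL_POOL_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._inshape = x.shape
        if self.variant == "GAP":
            return x.mean(axis=(2, 3))
        if self.variant == "GMP":
            flat = x.reshape(x.shape[0], x.shape[1], -1)
            self._argmax = flat.argmax(axis=-1)
            return flat.max(axis=-1)
        x32 = x.astype(np.float32 if x.dtype == np.float16 else x.dtype,
                       copy=False)
        m = x32.max(axis=(2, 3), keepdims=True)
        e = np.exp(x32 - m)
        s = e.sum(axis=(2, 3), keepdims=True)
        self._softmax = e / s
        out = m[:, :, 0, 0] + np.log(s[:, :, 0, 0])
        return out.astype(x.dtype, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        if self.variant == "GAP":
            return np.broadcast_to(
                grad[:, :, None, None] / (h * w), self._inshape
            ).astype(grad.dtype).copy()
        if self.variant == "GMP":
            dflat = np.zeros((n, c, h * w), dtype=grad.dtype)
            np.put_along_axis(dflat, self._argmax[..., None],
                              grad[..., None], axis=-1)
            return dflat.reshape(self._inshape)
        return (self._softmax * grad[:, :, None, None].astype(np.float32)) \
            .astype(grad.dtype, copy=False)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Param(
            rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features))
        )
        self.bias = Param(np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        dt = self.compute_dtype
        x = x.astype(dt, copy=False)
        self._x = x
        return x @ self.weight.data.astype(dt) + self.bias.data.astype(dt)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dt = self.compute_dtype
        g = grad.astype(dt, copy=False)
        self.weight.grad += (self._x.T @ g).astype(np.float32)
        self.bias.grad += g.sum(axis=0).astype(np.float32)
        return g @ self.weight.data.astype(dt).T


class Dropout(Layer):
    """Inverted dropout: each hidden node is shut off with probability p
    during training and survivors are scaled by 1/(1-p); at evaluation the
    layer is the identity."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p)
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


# ---------------------------------------------------------------------------
# Shape inference and parameter counting (closed form)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StageShape:
    stage: str
    channels: int
    height: int
    width: int


def infer_shapes(config: ArchitectureConfig) -> list[StageShape]:
    """Spatial bookkeeping through the network: each valid conv shrinks a
    side by (w-1)*l, each 2x2 pool halves it (floor)."""
    side = config.input_side
    channels = 3
    shapes: list[StageShape] = []
    for bi, blk in enumerate(config.blocks, start=1):
        for ci, (w, l) in enumerate(((blk.w1, blk.l1), (blk.w2, blk.l2)),
                                    start=1):
            side = side - (w - 1) * l
            if side < 1:
                raise ValueError(
                    f"block {bi} conv {ci} reduces the spatial side to "
                    f"{side} (< 1); shrink kernels/dilations or grow the input"
                )
            channels = blk.out_channels
            shapes.append(StageShape(f"block{bi}.conv{ci}", channels, side,
                                     side))
        side = side // 2
        if side < 1:
            raise ValueError(
                f"block {bi} pooling reduces the spatial side below 1"
            )
        shapes.append(StageShape(f"block{bi}.pool", channels, side, side))
    shapes.append(StageShape("global_pool", channels, 1, 1))
    return shapes


def count_parameters(config: ArchitectureConfig) -> int:
    """Closed-form trainable-parameter count.

    Per block: w1^2*C_in*C_out + C_out (bias) [+ 2*C_out BN affine]
             + w2^2*C_out^2   + C_out (bias) [+ 2*C_out BN affine];
    head: M*h1 + h1 + h1*3 + 3.
    """
    total = 0
    c_in = 3
    for blk in config.blocks:
        c = blk.out_channels
        total += blk.w1 ** 2 * c_in * c + c
        total += blk.w2 ** 2 * c * c + c
        if blk.use_bn:
            total += 4 * c
        c_in = c
    m = config.feature_channels
    h1 = config.hidden_width
    total += m * h1 + h1
    total += h1 * config.num_classes + config.num_classes
    return total


# ---------------------------------------------------------------------------
# The assembled model
# ---------------------------------------------------------------------------

class Network:
    """A trainable model handle built from an :class:`ArchitectureConfig`.

    Holds the layer stack, the input-preprocessing constants set by the
    trainer (per-channel mean/sd after the color-space transform), and
    save/load to ``.npz`` with a JSON config sidecar.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        infer_shapes(config)  # validates spatial bookkeeping, raises early
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        c_in = 3
        for blk in config.blocks:
            self.layers.append(
                DilatedConv2d(c_in, blk.out_channels, blk.w1, blk.l1, rng))
            if blk.use_bn:
                self.layers.append(BatchNorm2d(blk.out_channels))
            self.layers.append(ReLU())
            self.layers.append(
                DilatedConv2d(blk.out_channels, blk.out_channels, blk.w2,
                              blk.l2, rng))
            if blk.use_bn:
                self.layers.append(BatchNorm2d(blk.out_channels))
            self.layers.append(ReLU())
            self.layers.append(MaxPool2x2())
            c_in = blk.out_channels
        self.layers.append(GlobalPool(config.global_pool))
        self.layers.append(Dense(config.feature_channels, config.hidden_width,
                                 rng))
        self.layers.append(ReLU())
        self.layers.append(Dropout(config.dropout_rate, rng))
        self.layers.append(Dense(config.hidden_width, config.num_classes, rng))
        # preprocessing constants; identity until the trainer sets them
        self.input_mean = np.zeros(3, dtype=np.float32)
        self.input_sd = np.ones(3, dtype=np.float32)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_compute_dtype(self, dtype) -> None:
        for layer in self.layers:
            layer.compute_dtype = dtype

    # -- forward ------------------------------------------------------------

    def preprocess(self, batch: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) color-space-transformed patches -> standardized NCHW."""
        x = (batch - self.input_mean) / self.input_sd
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for an NCHW batch (already preprocessed)."""
        for layer in self.layers:
            x = layer.forward(x, training)
        if x.dtype == np.float16:
            x = x.astype(np.float32)
        return x

    def backward(self, grad: np.ndarray) -> None:
        g = grad
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1."""
        logits = self.forward(x, training=False).astype(np.float64)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p.data
        bi = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                arrays[f"bn_{bi}_mean"] = layer.running_mean
                arrays[f"bn_{bi}_var"] = layer.running_var
                bi += 1
        arrays["input_mean"] = self.input_mean
        arrays["input_sd"] = self.input_sd
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Network":
        path = Path(path)
        config = ArchitectureConfig.from_dict(
            json.loads(path.with_suffix(path.suffix + ".json").read_text())
        )
        net = cls(config, seed=seed)
        with np.load(path) as data:
            for i, p in enumerate(net.params()):
                p.data[...] = data[f"param_{i}"]
            bi = 0
            for layer in net.layers:
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = data[f"bn_{bi}_mean"]
                    layer.running_var[...] = data[f"bn_{bi}_var"]
                    bi += 1
            net.input_mean = data["input_mean"].astype(np.float32)
            net.input_sd = data["input_sd"].astype(np.float32)
        return net


def build_network(config: ArchitectureConfig, seed: int = 0) -> Network:
    """Instantiate a trainable model from a configuration."""
    return Network(config, seed=seed)
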