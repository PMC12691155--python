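"""Residual classifier with pluggable attention for candling images.

The network is a canonical 34-layer residual network (basic blocks in a
3/4/6/3 stage layout) ending in a 3-way classification head for
{unfertilized, live, abnormal}. Each basic block computes

    y = act( F(x, {W_i}) + W_s x )

where ``F`` is a conv-BN-ReLU-conv-BN branch and ``W_s`` is an identity
shortcut, or a 1x1 projection when the stride or channel count changes.

An attention module can be inserted inside every block, after the
convolution stack and before the shortcut addition:

* CBAM — cascaded channel and spatial gates:
  ``Mc(F) = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))`` with spatial
  pooling and a weight-shared two-layer MLP; ``F' = Mc(F) * F``;
  ``Ms(F') = sigmoid(conv7x7([AvgPool(F'); MaxPool(F')]))`` with channel
  pooling; ``F'' = Ms(F') * F'``. All products are elementwise with
  broadcasting.
* SE — squeeze (global average pool) and excitation (2-layer MLP +
  sigmoid) producing per-channel gates.
* CA — coordinate attention: directional average pools along height and
  width, a shared 1x1 bottleneck with h-swish, and separate per-direction
  sigmoid gates.

Since every gate is a sigmoid output, gates lie strictly in (0, 1) and the
gated feature map never exceeds the input elementwise in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Identity,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    concat,
)

__all__ = [
    "ModelSpec",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "SqueezeExcitation",
    "CoordinateAttention",
    "BasicBlock",
    "ResNet",
    "build_classifier",
    "ATTENTION_KINDS",
]

ATTENTION_KINDS = ("none", "se", "ca", "cbam")

#: stage layout of the 34-layer residual network (basic blocks per stage)
RESNET34_STAGES = (3, 4, 6, 3)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for :func:`build_classifier`.

    ``base_width`` scales every stage's channel count; 64 is the canonical
    width, smaller values give desk-scale variants for quick experiments.
    """

    depth: int = 34
    attention: str = "cbam"
    num_classes: int = 3
    reduction_ratio: int = 16
    ca_reduction_ratio: int = 32
    spatial_kernel: int = 7
    base_width: int = 64

    def __post_init__(self):
        if self.depth != 34:
            raise ValueError(f"only depth 34 is supported, got {self.depth}")
        if self.attention not in ATTENTION_KINDS:
            raise ValueError(f"attention must be one of {ATTENTION_KINDS}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.spatial_kernel != 7:
            raise ValueError("the spatial attention kernel is fixed at 7")
        if self.base_width < 1 or self.reduction_ratio < 1:
            raise ValueError("base_width and reduction_ratio must be >= 1")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "attention": self.attention,
            "num_classes": self.num_classes,
            "reduction_ratio": self.reduction_ratio,
            "ca_reduction_ratio": self.ca_reduction_ratio,
            "spatial_kernel": self.spatial_kernel,
            "base_width": self.base_width,
        }


class ChannelAttention(Module):
    """Channel gate from spatially pooled statistics (shared MLP)."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        """Return Mc(x) with shape (N, C, 1, 1); values in (0, 1)."""
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        s = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return s.sigmoid().reshape(n, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class SpatialAttention(Module):
    """Spatial gate from channel-pooled statistics via a 7x7 convolution."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("spatial kernel must be odd")
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        """Return Ms(x) with shape (N, 1, H, W); same-size padding."""
        pooled = concat([x.mean(axis=1, keepdims=True),
                         x.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class CBAM(Module):
    """Cascaded channel-then-spatial attention."""

    def __init__(self, channels: int, reduction: int = 16, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(kernel_size, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.channel(x)
        return self.spatial(x)


class SqueezeExcitation(Module):
    """Squeeze-and-excitation channel gate (global average pool + MLP)."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        s = self.fc2(self.fc1(x.mean(axis=(2, 3))).relu()).sigmoid()
        return s.reshape(n, c, 1, 1) * x


def _hswish(x: Tensor) -> Tensor:
    return x * ((x + 3.0).clip(0.0, 6.0) * (1.0 / 6.0))


class CoordinateAttention(Module):
    """Coordinate attention: direction-aware factorised channel gating."""

    def __init__(self, channels: int, reduction: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(4, channels // reduction)
        self.conv1 = Conv2d(channels, hidden, 1, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.conv_h = Conv2d(hidden, channels, 1, rng=rng)
        self.conv_w = Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        pool_h = x.mean(axis=3, keepdims=True)                   # (N,C,H,1)
        pool_w = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (N,C,W,1)
        y = concat([pool_h, pool_w], axis=2)                     # (N,C,H+W,1)
        y = _hswish(self.bn1(self.conv1(y)))
        # split back into the two directional descriptors
        a_h = self._slice_rows(y, 0, h)                          # (N,hid,H,1)
        a_w = self._slice_rows(y, h, h + w).transpose(0, 1, 3, 2)  # (N,hid,1,W)
        gate_h = self.conv_h(a_h).sigmoid()                      # (N,C,H,1)
        gate_w = self.conv_w(a_w).sigmoid()                      # (N,C,1,W)
        return x * gate_h * gate_w

    @staticmethod
    def _slice_rows(x: Tensor, a: int, b: int) -> Tensor:
        """Differentiable slice along axis 2."""
        def backward(g):
            full = np.zeros(x.shape, dtype=np.float32)
            full[:, :, a:b] = g
            x._accumulate(full)

        out = Tensor(x.data[:, :, a:b])
        if x.requires_grad or x._parents:
            out.requires_grad = x.requires_grad
            out._parents = (x,)
            out._backward = backward
        return out


def _make_attention(kind: str, channels: int, spec: ModelSpec,
                    rng: np.random.Generator) -> Module:
    if kind == "none":
        return Identity()
    if kind == "cbam":
        return CBAM(channels, spec.reduction_ratio, spec.spatial_kernel, rng=rng)
    if kind == "se":
        return SqueezeExcitation(channels, spec.reduction_ratio, rng=rng)
    if kind == "ca":
        return CoordinateAttention(channels, spec.ca_reduction_ratio, rng=rng)
    raise ValueError(f"unknown attention kind: {kind}")


class BasicBlock(Module):
    """Two 3x3 convolutions with a (projected) identity shortcut.

    The attention module, when present, rescales the residual branch output
    before it is added to the shortcut.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 attention: Module | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride,
                            padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.attention = attention if attention is not None else Identity()
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride,
                       bias=False, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = Identity()

    def forward(self, x: Tensor) -> Tensor:
        branch = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        branch = self.attention(branch)
        return (branch + self.shortcut(x)).relu()


class ResNet(Module):
    """34-layer residual network with optional per-block attention."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        w = spec.base_width
        self.conv1 = Conv2d(3, w, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(w)
        self.maxpool = MaxPool2d(3, 2, 1)
        widths = [w, 2 * w, 4 * w, 8 * w]
        strides = [1, 2, 2, 2]
        stages = []
        in_ch = w
        for n_blocks, out_ch, stage_stride in zip(RESNET34_STAGES, widths, strides):
            blocks = []
            for i in range(n_blocks):
                stride = stage_stride if i == 0 else 1
                att = _make_attention(spec.attention, out_ch, spec, rng)
                blocks.append(BasicBlock(in_ch, out_ch, stride, att, rng=rng))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        self.stages = stages
        self.fc = Linear(widths[-1], spec.num_classes, rng=rng, std=0.01)

    def forward(self, x: Tensor) -> Tensor:
        x = self.maxpool(self.bn1(self.conv1(x)).relu())
        for stage in self.stages:
            x = stage(x)
        x = x.mean(axis=(2, 3))  # global average pool
        return self.fc(x)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class indices for a (N, 3, H, W) float array (eval mode)."""
        self.eval()
        preds = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[start : start + batch_size]))
            preds.append(logits.data.argmax(axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)


def build_classifier(spec: ModelSpec, seed: int) -> ResNet:
    """Build a seeded classifier; identical (spec, seed) gives identical
    initial weights."""
    return ResNet(spec, rng=np.random.default_rng(seed))
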