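"""Encoder backbones producing the four-level feature pyramid f1..f4.

Three interchangeable families:

``pvt``
    A pyramid-vision-transformer style encoder (non-overlapping patch
    embeddings, spatial-reduction attention, four stages at strides
    4/8/16/32).  Default channel widths (64, 128, 320, 512).
``resnet50``
    The classic bottleneck CNN; conv2_x..conv5_x outputs serve as f1..f4
    with channels (256, 512, 1024, 2048).
``tiny``
    A small purely-convolutional pyramid for CPU tests and desk-scale
    training; channels default (16, 32, 64, 96).

All families satisfy the same contract: for an input of H x W (each divisible
by 32), level f_i has spatial size (H / 2^{i+1}, W / 2^{i+1}) and the channel
widths are non-decreasing with depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor, functional as F

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = {
    "pvt": (64, 128, 320, 512),
    "resnet50": (256, 512, 1024, 2048),
    "tiny": (16, 32, 64, 96),
}


@dataclass
class FeaturePyramid:
    """Encoder features f1..f4 at strides 4, 8, 16 and 32."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3, self.f4))

    @property
    def channels(self) -> tuple[int, int, int, int]:
        return tuple(f.shape[1] for f in self)


@dataclass
class BackboneSpec:
    family: str = "pvt"
    channels: tuple[int, int, int, int] | None = None
    pretrained: bool = False

    def resolved_channels(self) -> tuple[int, int, int, int]:
        ch = tuple(self.channels) if self.channels else DEFAULT_CHANNELS[self.family]
        if len(ch) != 4 or any(c <= 0 for c in ch):
            raise ConfigurationError(f"need 4 positive channel widths, got {ch}")
        if list(ch) != sorted(ch):
            raise ConfigurationError(f"channel widths must be non-decreasing, got {ch}")
        return ch


def _validate_input(x: Tensor) -> None:
    if x.ndim != 4 or x.shape[1] != 3:
        raise ShapeError(f"expected a B x 3 x H x W image batch, got {x.shape}")
    _, _, h, w = x.shape
    if h % 32:
        raise ShapeError(f"image height {h} is not divisible by 32")
    if w % 32:
        raise ShapeError(f"image width {w} is not divisible by 32")
    if not np.all(np.isfinite(x.data)):
        raise ValueError("image tensor contains non-finite values")


class Encoder(nn.Module):
    """Base class: validates the input then delegates to `_features`."""

    family = "abstract"

    def __init__(self, channels: tuple[int, int, int, int]):
        super().__init__()
        self.channels = channels

    def forward(self, x: Tensor) -> FeaturePyramid:
        _validate_input(x)
        f1, f2, f3, f4 = self._features(x)
        return FeaturePyramid(f1, f2, f3, f4)


class TinyEncoder(Encoder):
    """Eight 3x3 conv blocks, two per stride level; fast enough for CPU tests."""

    family = "tiny"

    def __init__(self, channels=DEFAULT_CHANNELS["tiny"]):
        super().__init__(channels)
        c1, c2, c3, c4 = channels
        B = nn.ConvBlock
        self.stage1 = nn.Sequential(B(3, c1, stride=2), B(c1, c1, stride=2))
        self.stage2 = nn.Sequential(B(c1, c2, stride=2), B(c2, c2))
        self.stage3 = nn.Sequential(B(c2, c3, stride=2), B(c3, c3))
        self.stage4 = nn.Sequential(B(c3, c4, stride=2), B(c4, c4))

    def _features(self, x):
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return f1, f2, f3, f4


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int = 1):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, bias=False)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.down = nn.Identity()

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        return (h + self.down(x)).relu()


class ResNet50Encoder(Encoder):
    """ResNet-50 layout; f1..f4 are the conv2_x..conv5_x block outputs."""

    family = "resnet50"
    _depths = (3, 4, 6, 3)
    _widths = (64, 128, 256, 512)

    def __init__(self, channels=DEFAULT_CHANNELS["resnet50"]):
        expected = tuple(w * _Bottleneck.expansion for w in self._widths)
        if tuple(channels) != expected:
            raise ConfigurationError(
                f"resnet50 channel widths are fixed at {expected}, got {tuple(channels)}"
            )
        super().__init__(channels)
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(64)
        in_ch = 64
        for i, (depth, width) in enumerate(zip(self._depths, self._widths)):
            blocks = []
            for j in range(depth):
                stride = 2 if (j == 0 and i > 0) else 1
                blocks.append(_Bottleneck(in_ch, width, stride))
                in_ch = width * _Bottleneck.expansion
            setattr(self, f"layer{i + 1}", nn.Sequential(*blocks))

    def _features(self, x):
        h = self.stem_bn(self.stem_conv(x)).relu()
        h = F.max_pool2d(h, 3, 2, padding=1)
        f1 = self.layer1(h)
        f2 = self.layer2(f1)
        f3 = self.layer3(f2)
        f4 = self.layer4(f3)
        return f1, f2, f3, f4


def _softmax(t: Tensor, axis: int = -1) -> Tensor:
    m = t.max(axis=axis, keepdims=True)
    e = (t - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


class _SRAttention(nn.Module):
    """Multi-head self-attention with spatial reduction of keys/values."""

    def __init__(self, dim: int, heads: int, sr_ratio: int):
        super().__init__()
        if dim % heads:
            raise ConfigurationError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.sr = dim, heads, sr_ratio
        self.q = nn.Linear(dim, dim)
        self.kv = nn.Linear(dim, 2 * dim)
        self.proj = nn.Linear(dim, dim)
        if sr_ratio > 1:
            self.sr_conv = nn.Conv2d(dim, dim, sr_ratio, stride=sr_ratio, padding=0)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        B, N, C = x.shape
        H, W = hw
        hd = C // self.heads
        q = self.q(x).reshape(B, N, self.heads, hd).transpose(0, 2, 1, 3)
        if self.sr > 1:
            xm = x.transpose(0, 2, 1).reshape(B, C, H, W)
            xr = self.sr_conv(xm)
            n2 = xr.shape[2] * xr.shape[3]
            xr = xr.reshape(B, C, n2).transpose(0, 2, 1)
            src = self.sr_norm(xr)
        else:
            src = x
        M = src.shape[1]
        kv = self.kv(src).reshape(B, M, 2, self.heads, hd).transpose(2, 0, 3, 1, 4)
        k, v = kv[0], kv[1]
        att = _softmax((q @ k.transpose(0, 1, 3, 2)) * (hd**-0.5), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.proj(out)


class _PVTBlock(nn.Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, mlp_ratio: int = 4):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _SRAttention(dim, heads, sr_ratio)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, dim * mlp_ratio)
        self.fc2 = nn.Linear(dim * mlp_ratio, dim)

    def forward(self, x, hw):
        x = x + self.attn(self.norm1(x), hw)
        return x + self.fc2(self.fc1(self.norm2(x)).relu())


class PVTEncoder(Encoder):
    """PVT-style four-stage transformer pyramid (v1-tiny-like configuration)."""

    family = "pvt"
    _depths = (2, 2, 2, 2)
    _heads = (1, 2, 5, 8)
    _sr_ratios = (8, 4, 2, 1)

    def __init__(self, channels=DEFAULT_CHANNELS["pvt"]):
        super().__init__(channels)
        for c, h in zip(channels, self._heads):
            if c % h:
                raise ConfigurationError(
                    f"pvt channel width {c} must be divisible by its head count {h}"
                )
        in_ch = 3
        for i, c in enumerate(channels):
            patch = 4 if i == 0 else 2
            setattr(self, f"embed{i + 1}",
                    nn.Conv2d(in_ch, c, patch, stride=patch, padding=0))
            setattr(self, f"enorm{i + 1}", nn.LayerNorm(c))
            setattr(self, f"blocks{i + 1}", nn.Sequential(*[
                _PVTBlock(c, self._heads[i], self._sr_ratios[i])
                for _ in range(self._depths[i])
            ]))
            setattr(self, f"onorm{i + 1}", nn.LayerNorm(c))
            in_ch = c

    def _features(self, x):
        feats = []
        h = x
        for i in range(4):
            embed = getattr(self, f"embed{i + 1}")
            hmap = embed(h)
            B, C, H, W = hmap.shape
            tok = hmap.reshape(B, C, H * W).transpose(0, 2, 1)
            tok = getattr(self, f"enorm{i + 1}")(tok)
            for blk in getattr(self, f"blocks{i + 1}").layers:
                tok = blk(tok, (H, W))
            tok = getattr(self, f"onorm{i + 1}")(tok)
            h = tok.transpose(0, 2, 1).reshape(B, C, H, W)
            feats.append(h)
        return tuple(feats)


_FAMILIES = {"tiny": TinyEncoder, "resnet50": ResNet50Encoder, "pvt": PVTEncoder}


def build_backbone(spec: BackboneSpec) -> Encoder:
    """Construct an encoder from a :class:`BackboneSpec`.

    `pretrained=True` degrades to random initialisation with a warning: no
    weight source is bundled with the package.
    """
    if spec.family not in _FAMILIES:
        raise ConfigurationError(
            f"unknown backbone family {spec.family!r}; choose from {sorted(_FAMILIES)}"
        )
    channels = spec.resolved_channels()
    enc = _FAMILIES[spec.family](channels)
    if spec.pretrained:
        logger.warning(
            "pretrained weights for %r are unavailable; using random initialisation",
            spec.family,
        )
    return enc


def encode(encoder: Encoder, x: Tensor) -> FeaturePyramid:
    """Run the encoder on an image batch, returning the feature pyramid."""
    return encoder(x)
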