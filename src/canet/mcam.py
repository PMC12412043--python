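"""Multiscale context extraction on the shallowest feature level f1.

Two sequential multi-branch stages preserve the stride-4 resolution while
widening the receptive field:

1. parallel convolutions with kernel sizes {1, 3, 7, 11}, concatenated;
2. parallel 3x3 dilated convolutions with rates {1, 3, 7, 11} (padding equal
   to the rate keeps the spatial size), concatenated.

A 1x1-projected residual of the original f1 is added back (ReLU on the sum),
and CBAM-style channel-then-spatial attention gates the fused feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .errors import ConfigurationError
from .nn import Tensor, concat, functional as F


@dataclass
class McamConfig:
    kernel_sizes: tuple[int, ...] = (1, 3, 7, 11)
    dilation_rates: tuple[int, ...] = (1, 3, 7, 11)
    branch_channels: int | None = None  # default: C1 / n_branches
    cbam_reduction: int = 16
    sa_kernel: int = 7
    batch_norm: bool = True

    def validate(self) -> None:
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigurationError(
                f"mcam.kernel_sizes must be odd, got {self.kernel_sizes}"
            )
        if any(d < 1 for d in self.dilation_rates):
            raise ConfigurationError(
                f"mcam.dilation_rates must be >= 1, got {self.dilation_rates}"
            )


@dataclass
class McamIntermediates:
    branch1_outputs: list[Tensor]
    f1_prime: Tensor
    branch2_outputs: list[Tensor]
    f1_dprime: Tensor
    fr: Tensor
    f_prime: Tensor
    fmcam: Tensor


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gate from average- and max-pooled descriptors."""

    def __init__(self, channels: int, reduction: int):
        super().__init__()
        if reduction >= channels:
            raise ConfigurationError(
                f"cbam reduction {reduction} must be < channel count {channels}"
            )
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Conv2d(channels, hidden, 1)
        self.fc2 = nn.Conv2d(hidden, channels, 1)

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        logits = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return logits.sigmoid()

    def forward(self, x):
        return x * self.gate(x)


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gate from channel mean/max maps through a 7x7 conv."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel)

    def gate(self, x: Tensor) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)],
                        axis=1)
        return self.conv(pooled).sigmoid()

    def forward(self, x):
        return x * self.gate(x)


class MCAM(nn.Module):
    def __init__(self, in_channels: int, cfg: McamConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or McamConfig()
        cfg.validate()
        nb = len(cfg.kernel_sizes)
        bc = cfg.branch_channels or max(1, in_channels // nb)
        self.branch_channels = bc
        bn = cfg.batch_norm
        for i, k in enumerate(cfg.kernel_sizes):
            setattr(self, f"mk{i}", nn.ConvBlock(in_channels, bc, k, norm=bn))
        width1 = bc * nb
        for i, d in enumerate(cfg.dilation_rates):
            setattr(self, f"dil{i}", nn.ConvBlock(width1, bc, 3, dilation=d, norm=bn))
        width2 = bc * len(cfg.dilation_rates)
        self.res_conv = nn.Conv2d(in_channels, width2, 1, bias=not bn)
        self.res_bn = nn.BatchNorm2d(width2) if bn else nn.Identity()
        self.fuse_conv = nn.Conv2d(width2, width2, 1, bias=not bn)
        self.fuse_bn = nn.BatchNorm2d(width2) if bn else nn.Identity()
        self.ca = ChannelAttention(width2, cfg.cbam_reduction)
        self.sa = SpatialAttention(cfg.sa_kernel)
        self.out_channels = width2

    # stages -- exposed for unit tests ---------------------------------------

    def multikernel_branch(self, f1: Tensor):
        outs = [getattr(self, f"mk{i}")(f1) for i in range(len(self.cfg.kernel_sizes))]
        return concat(outs, axis=1), outs

    def dilated_branch(self, f1_prime: Tensor):
        outs = [getattr(self, f"dil{i}")(f1_prime)
                for i in range(len(self.cfg.dilation_rates))]
        return concat(outs, axis=1), outs

    def residual_fuse(self, f1: Tensor, f1_dprime: Tensor):
        fr = self.res_bn(self.res_conv(f1))
        assert fr.shape[1] == f1_dprime.shape[1], "residual width mismatch (bug)"
        f_prime = (fr + self.fuse_bn(self.fuse_conv(f1_dprime))).relu()
        return f_prime, fr

    def dual_attention(self, f_prime: Tensor) -> Tensor:
        return self.sa(self.ca(f_prime))

    def forward(self, f1: Tensor):
        f1_prime, b1 = self.multikernel_branch(f1)
        f1_dprime, b2 = self.dilated_branch(f1_prime)
        f_prime, fr = self.residual_fuse(f1, f1_dprime)
        fmcam = self.dual_attention(f_prime)
        return fmcam, McamIntermediates(b1, f1_prime, b2, f1_dprime, fr, f_prime, fmcam)


def mcam_forward(f1: Tensor, cfg: McamConfig | None = None,
                 module: MCAM | None = None):
    if module is None:
        module = MCAM(f1.shape[1], cfg)
    return module(f1)
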