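"""Residual fusion of the deep (CAM) and shallow (MCAM) streams + prediction head.

The CAM output lives at stride 8 and the MCAM output at stride 4; the deep
stream is bilinearly upsampled x2 so the two can be concatenated:

    fcon = Concat(Up(fcam), fmcam)
    fx'  = BN(Conv3(ReLU(BN(Conv3(fcon)))))        main path
    fres = BN(Conv1(fcon))                          shortcut
    frfm = Conv(ReLU(fx' + fres))                   3x3 conv-BN-ReLU block

The prediction head maps frfm to a single-channel logit map and restores the
input resolution with a x4 bilinear upsample.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .errors import ShapeError
from .nn import Tensor, concat, functional as F


@dataclass
class RfmConfig:
    mid_channels: int = 64
    upsample_mode: str = "bilinear"
    batch_norm: bool = True


class RFM(nn.Module):
    def __init__(self, cam_channels: int, mcam_channels: int,
                 cfg: RfmConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or RfmConfig()
        mid, bn = cfg.mid_channels, cfg.batch_norm
        cin = cam_channels + mcam_channels
        self.conv_a = nn.Conv2d(cin, mid, 3, bias=not bn)
        self.bn_a = nn.BatchNorm2d(mid) if bn else nn.Identity()
        self.conv_b = nn.Conv2d(mid, mid, 3, bias=not bn)
        self.bn_b = nn.BatchNorm2d(mid) if bn else nn.Identity()
        self.short_conv = nn.Conv2d(cin, mid, 1, bias=not bn)
        self.short_bn = nn.BatchNorm2d(mid) if bn else nn.Identity()
        self.out_block = nn.ConvBlock(mid, mid, 3, norm=bn)
        self.out_channels = mid

    def forward(self, fcam: Tensor, fmcam: Tensor) -> Tensor:
        up = F.resize2d(fcam, 2, self.cfg.upsample_mode)
        if up.shape[2:] != fmcam.shape[2:]:
            raise ShapeError(
                f"upsampled deep stream {up.shape[2:]} does not match the shallow "
                f"stream {fmcam.shape[2:]}"
            )
        fcon = concat([up, fmcam], axis=1)
        fx = self.bn_b(self.conv_b(self.bn_a(self.conv_a(fcon)).relu()))
        fres = self.short_bn(self.short_conv(fcon))
        return self.out_block((fx + fres).relu())


class PredictHead(nn.Module):
    """1x1 conv to one channel + x4 bilinear upsample back to image resolution."""

    def __init__(self, in_channels: int, upsample_mode: str = "bilinear"):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, 1, 1)
        self.mode = upsample_mode

    def forward(self, frfm: Tensor) -> Tensor:
        return F.resize2d(self.conv(frfm), 4, self.mode)


def rfm_forward(fcam: Tensor, fmcam: Tensor, cfg: RfmConfig | None = None,
                module: RFM | None = None) -> Tensor:
    if module is None:
        module = RFM(fcam.shape[1], fmcam.shape[1], cfg)
    return module(fcam, fmcam)


def predict_head(frfm: Tensor, module: PredictHead | None = None) -> Tensor:
    if module is None:
        module = PredictHead(frfm.shape[1])
    return module(frfm)
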