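"""Cascaded aggregation of the three deepest pyramid levels.

Top-down decoder path: high-level semantics (f4, then f3) multiplicatively
gate the shallower features before each aggregation stage, so that regions
the deep features consider salient are amplified and background is
suppressed.  Two stages:

* first path:   f3' = Conv(Up(f4) * f3);  f3'' = Concat(Conv(Up(f4)), f3')
* second path:  f2' = Conv(Up2(f4) * Conv(Up(f3) * f2));
                f2'' = Concat(Conv(Conv(Up(s))), f2')  with s the first-path
                output (default) or f3' (configurable — the source description
                is ambiguous about which tensor the second stage consumes)
* output:       fcam = Conv(Conv(f2'')), at stride 8.

Every `Conv` is a 3x3 conv + BN + ReLU block with a shared internal width;
1x1 projections align channel counts before each elementwise product.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .errors import ConfigurationError
from .nn import Tensor, concat, functional as F

VALID_SOURCES = ("f3_agg", "f3_prime")


@dataclass
class CamConfig:
    mid_channels: int = 64
    second_path_source: str = "f3_agg"
    upsample_mode: str = "bilinear"
    batch_norm: bool = True  # disabled only for equation-oracle analysis

    def validate(self) -> None:
        if self.mid_channels <= 0:
            raise ConfigurationError("cam.mid_channels must be positive")
        if self.second_path_source not in VALID_SOURCES:
            raise ConfigurationError(
                f"cam.second_path_source must be one of {VALID_SOURCES}, "
                f"got {self.second_path_source!r}"
            )


@dataclass
class CamIntermediates:
    """Every named tensor of the cascade, exposed for tests and inspection."""

    f3_prime: Tensor
    f3_agg: Tensor
    f2_prime: Tensor
    f2_agg: Tensor
    fcam: Tensor


class CAM(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int], cfg: CamConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or CamConfig()
        cfg.validate()
        c2, c3, c4 = in_channels
        mid, bn = cfg.mid_channels, cfg.batch_norm
        # 1x1 channel-aligning projections (no norm/act: pure reshaping of width)
        self.proj2 = nn.Conv2d(c2, mid, 1)
        self.proj3 = nn.Conv2d(c3, mid, 1)
        self.proj4 = nn.Conv2d(c4, mid, 1)
        mk = lambda cin: nn.ConvBlock(cin, mid, 3, norm=bn)
        self.conv_f3 = mk(mid)          # Conv of the first guided product
        self.conv_up4 = mk(mid)         # Conv(Up(f4)) in the first aggregation
        self.conv_f2_inner = mk(mid)    # inner Conv of the nested second product
        self.conv_f2_outer = mk(mid)    # outer Conv of the nested second product
        src_ch = 2 * mid if cfg.second_path_source == "f3_agg" else mid
        self.conv_src_a = mk(src_ch)    # Conv(Conv(Up(source))) pair
        self.conv_src_b = mk(mid)
        self.out_a = mk(2 * mid)        # two transform convs on f2''
        self.out_b = mk(mid)

    # individual operations -- exposed for unit tests ------------------------

    def guided_refine_f3(self, f3: Tensor, f4: Tensor) -> Tensor:
        up4 = F.resize2d(self.proj4(f4), 2, self.cfg.upsample_mode)
        return self.conv_f3(up4 * self.proj3(f3))

    def aggregate_first_path(self, f3_prime: Tensor, f4: Tensor) -> Tensor:
        up4 = F.resize2d(self.proj4(f4), 2, self.cfg.upsample_mode)
        return concat([self.conv_up4(up4), f3_prime], axis=1)

    def guided_refine_f2(self, f2: Tensor, f3: Tensor, f4: Tensor) -> Tensor:
        up3 = F.resize2d(self.proj3(f3), 2, self.cfg.upsample_mode)
        inner = self.conv_f2_inner(up3 * self.proj2(f2))
        up4 = F.resize2d(self.proj4(f4), 4, self.cfg.upsample_mode)
        return self.conv_f2_outer(up4 * inner)

    def aggregate_second_path(self, f2_prime: Tensor, f3_source: Tensor) -> Tensor:
        up = F.resize2d(f3_source, 2, self.cfg.upsample_mode)
        return concat([self.conv_src_b(self.conv_src_a(up)), f2_prime], axis=1)

    # full cascade ------------------------------------------------------------

    def forward(self, f2: Tensor, f3: Tensor, f4: Tensor):
        f3_prime = self.guided_refine_f3(f3, f4)
        f3_agg = self.aggregate_first_path(f3_prime, f4)
        f2_prime = self.guided_refine_f2(f2, f3, f4)
        source = f3_agg if self.cfg.second_path_source == "f3_agg" else f3_prime
        f2_agg = self.aggregate_second_path(f2_prime, source)
        fcam = self.out_b(self.out_a(f2_agg))
        return fcam, CamIntermediates(f3_prime, f3_agg, f2_prime, f2_agg, fcam)


def cam_forward(f2: Tensor, f3: Tensor, f4: Tensor, cfg: CamConfig | None = None,
                module: CAM | None = None):
    """Functional entry point: builds (or reuses) a CAM and runs the cascade."""
    if module is None:
        module = CAM((f2.shape[1], f3.shape[1], f4.shape[1]), cfg)
    return module(f2, f3, f4)
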