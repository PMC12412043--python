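"""Full network assembly: encoder + CAM + MCAM + RFM + prediction head.

Each of the three decoder modules can be toggled off to reproduce the
ablation lattice:

* ``use_cam=False``  — the deep stream is a 1x1-projected f2 (stride 8);
* ``use_mcam=False`` — the shallow stream is a 1x1-projected f1 (stride 4);
* ``use_rfm=False``  — fusion degrades to concatenation + a single conv block.

The bare-backbone baseline therefore is: projections of f1/f2, concatenation,
one conv, head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .backbone import BackboneSpec, FeaturePyramid, build_backbone
from .cam import CAM, CamConfig
from .mcam import MCAM, McamConfig
from .nn import Tensor, concat, functional as F
from .rfm import RFM, PredictHead, RfmConfig


@dataclass
class ModelConfig:
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    cam: CamConfig = field(default_factory=CamConfig)
    mcam: McamConfig = field(default_factory=McamConfig)
    rfm: RfmConfig = field(default_factory=RfmConfig)
    use_cam: bool = True
    use_mcam: bool = True
    use_rfm: bool = True


def tiny_model_config(**overrides) -> ModelConfig:
    """CPU-sized configuration used by the test-suite and desk-scale training."""
    cfg = ModelConfig(
        backbone=BackboneSpec(family="tiny"),
        cam=CamConfig(mid_channels=16),
        mcam=McamConfig(cbam_reduction=4),
        rfm=RfmConfig(mid_channels=16),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class CANet(nn.Module):
    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        self.encoder = build_backbone(cfg.backbone)
        c1, c2, c3, c4 = self.encoder.channels
        mid = cfg.cam.mid_channels

        if cfg.use_cam:
            self.cam = CAM((c2, c3, c4), cfg.cam)
            deep_ch = mid
        else:
            self.cam_proj = nn.ConvBlock(c2, mid, 1, norm=cfg.cam.batch_norm)
            deep_ch = mid
        if cfg.use_mcam:
            self.mcam = MCAM(c1, cfg.mcam)
            shallow_ch = self.mcam.out_channels
        else:
            self.mcam_proj = nn.ConvBlock(c1, mid, 1, norm=cfg.mcam.batch_norm)
            shallow_ch = mid
        if cfg.use_rfm:
            self.rfm = RFM(deep_ch, shallow_ch, cfg.rfm)
            head_ch = self.rfm.out_channels
        else:
            self.fuse = nn.ConvBlock(deep_ch + shallow_ch, cfg.rfm.mid_channels, 3,
                                     norm=cfg.rfm.batch_norm)
            head_ch = cfg.rfm.mid_channels
        self.head = PredictHead(head_ch, cfg.rfm.upsample_mode)

    def forward(self, x: Tensor) -> Tensor:
        """Image batch -> full-resolution logit map (B x 1 x H x W)."""
        pyr: FeaturePyramid = self.encoder(x)
        if self.cfg.use_cam:
            deep, _ = self.cam(pyr.f2, pyr.f3, pyr.f4)
        else:
            deep = self.cam_proj(pyr.f2)
        shallow = self.mcam(pyr.f1)[0] if self.cfg.use_mcam else self.mcam_proj(pyr.f1)
        if self.cfg.use_rfm:
            fused = self.rfm(deep, shallow)
        else:
            up = F.resize2d(deep, 2, self.cfg.rfm.upsample_mode)
            fused = self.fuse(concat([up, shallow], axis=1))
        return self.head(fused)

    def predict_proba(self, x: Tensor) -> Tensor:
        return self.forward(x).sigmoid()


def canet_forward(x: Tensor, model: CANet) -> Tensor:
    """End-to-end probability map for an image batch."""
    return model.predict_proba(x)
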