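"""Key-value configuration files.

Accepts flat dotted keys (``backbone.family: tiny``) or equivalently nested
YAML mappings; unknown keys raise so typos fail fast.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .backbone import BackboneSpec
from .cam import CamConfig
from .data import AugmentationPolicy
from .errors import ConfigurationError
from .mcam import McamConfig
from .model import ModelConfig
from .rfm import RfmConfig
from .trainer import TrainConfig


def _flatten(d: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


_TRAIN_KEYS = {"epochs", "batch_size", "lr", "optimizer", "patience",
               "val_fraction", "seed", "threshold", "min_delta"}
_AUG_KEYS = {"p_hflip", "p_vflip", "p_rot90", "p_jitter", "brightness",
             "contrast", "seed"}


def config_from_dict(flat: dict[str, object]) -> TrainConfig:
    flat = _flatten(flat)
    backbone = BackboneSpec()
    cam, mcam, rfm = CamConfig(), McamConfig(), RfmConfig()
    cfg = TrainConfig(model=ModelConfig(backbone=backbone, cam=cam, mcam=mcam, rfm=rfm))
    aug_kwargs: dict[str, object] = {}
    for key, value in flat.items():
        group, _, name = key.partition(".")
        if group == "backbone" and name in ("family", "pretrained"):
            setattr(backbone, name, value)
        elif group == "backbone" and name == "channels":
            backbone.channels = tuple(value)
        elif group == "cam" and name in vars(cam):
            setattr(cam, name, value)
        elif group == "mcam" and name in ("kernel_sizes", "dilation_rates"):
            setattr(mcam, name, tuple(value))
        elif group == "mcam" and name in vars(mcam):
            setattr(mcam, name, value)
        elif group == "rfm" and name in vars(rfm):
            setattr(rfm, name, value)
        elif group == "model" and name in ("use_cam", "use_mcam", "use_rfm"):
            setattr(cfg.model, name, bool(value))
        elif group == "loss" and name == "smooth_eps":
            cfg.loss_smooth_eps = float(value)
        elif group == "train" and name == "image_size":
            cfg.image_size = tuple(value)
        elif group == "train" and name in _TRAIN_KEYS:
            setattr(cfg, name, value)
        elif group == "augment" and name == "enabled":
            if value and cfg.augmentation is None:
                cfg.augmentation = AugmentationPolicy()
        elif group == "augment" and name in _AUG_KEYS:
            aug_kwargs[name] = value
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    if aug_kwargs:
        cfg.augmentation = AugmentationPolicy(**aug_kwargs)  # type: ignore[arg-type]
    return cfg


def load_config(path) -> TrainConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must be a mapping")
    return config_from_dict(raw)
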