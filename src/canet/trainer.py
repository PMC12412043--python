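"""Training loop, early stopping, checkpointing, evaluation and ablations.

Protocol defaults: Adam at learning rate 1e-4, batch size 16, up to 500
epochs with early stopping after 50 epochs without validation improvement,
images resized to 256 x 256.  The validation set for early stopping is a
seeded 10% carve-out of the training pairs (the monitored quantity is the
validation mean Dice); the held-out test split is never touched during
training.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .data import (AugmentationPolicy, SamplePair, augment, load_sample,
                   scan_dataset)
from .errors import ConfigurationError
from .losses import total_loss
from .metrics import MetricReport, binarize, evaluate_dataset
from .model import CANet, ModelConfig, tiny_model_config
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 16
    lr: float = 1e-4
    optimizer: str = "adam"
    patience: int = 50
    image_size: tuple[int, int] = (256, 256)
    val_fraction: float = 0.1
    seed: int = 42
    threshold: float = 0.5
    min_delta: float = 1e-5
    loss_smooth_eps: float = 1e-6
    model: ModelConfig = field(default_factory=ModelConfig)
    augmentation: AugmentationPolicy | None = None

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        h, w = self.image_size
        if h % 32 or w % 32:
            raise ConfigurationError(f"image_size {self.image_size} not divisible by 32")


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale defaults: tiny backbone, 96x96 images, a faster Adam."""
    cfg = TrainConfig(
        epochs=30, batch_size=8, lr=1e-3, patience=10, image_size=(96, 96),
        val_fraction=0.2, model=tiny_model_config(),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class TrainState:
    epoch: int = 0
    best_val_mdsc: float = -np.inf
    epochs_since_improvement: int = 0
    history: list[dict] = field(default_factory=list)


class EarlyStopper:
    """Stop after `patience` consecutive epochs without strict improvement."""

    def __init__(self, patience: int, min_delta: float = 1e-5):
        self.patience, self.min_delta = patience, min_delta
        self.best = -np.inf
        self.since_improvement = 0

    def update(self, value: float) -> bool:
        """Record one epoch's metric; return True when training should stop."""
        if value > self.best + self.min_delta:
            self.best = value
            self.since_improvement = 0
        else:
            self.since_improvement += 1
        return self.since_improvement >= self.patience


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: CANet, cfg: TrainConfig) -> None:
    state = model.state_dict()
    meta = {
        "seed": cfg.seed,
        "threshold": cfg.threshold,
        "image_size": list(cfg.image_size),
        "model": _model_config_dict(cfg.model),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def _model_config_dict(m: ModelConfig) -> dict:
    return {
        "backbone": {"family": m.backbone.family,
                     "channels": list(m.backbone.resolved_channels()),
                     "pretrained": m.backbone.pretrained},
        "cam": vars(m.cam).copy(),
        "mcam": {**vars(m.mcam), "kernel_sizes": list(m.mcam.kernel_sizes),
                 "dilation_rates": list(m.mcam.dilation_rates)},
        "rfm": vars(m.rfm).copy(),
        "use_cam": m.use_cam, "use_mcam": m.use_mcam, "use_rfm": m.use_rfm,
    }


def _model_config_from_dict(d: dict) -> ModelConfig:
    from .backbone import BackboneSpec
    from .cam import CamConfig
    from .mcam import McamConfig
    from .rfm import RfmConfig

    bb = d["backbone"]
    mc = {**d["mcam"]}
    mc["kernel_sizes"] = tuple(mc["kernel_sizes"])
    mc["dilation_rates"] = tuple(mc["dilation_rates"])
    return ModelConfig(
        backbone=BackboneSpec(bb["family"], tuple(bb["channels"]), bb["pretrained"]),
        cam=CamConfig(**d["cam"]), mcam=McamConfig(**mc), rfm=RfmConfig(**d["rfm"]),
        use_cam=d["use_cam"], use_mcam=d["use_mcam"], use_rfm=d["use_rfm"],
    )


def load_checkpoint(path) -> tuple[CANet, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = CANet(_model_config_from_dict(meta["model"]))
    try:
        model.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"checkpoint does not match model config: {exc}") from exc
    model.eval()
    return model, meta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_probs(model: CANet, images: np.ndarray, batch: int = 8) -> np.ndarray:
    """Eval-mode probability maps for a stack of images, batched."""
    out = []
    for i in range(0, len(images), batch):
        out.append(model.predict_proba(Tensor(images[i:i + batch])).data)
    return np.concatenate(out, axis=0)


def _validation_scores(model: CANet, images, masks, threshold) -> tuple[float, float]:
    model.eval()
    probs = _forward_probs(model, images)
    report = evaluate_dataset(list(zip(probs, masks)), threshold)
    model.train()
    return report.means["dsc"], report.means["iou"]


def train(cfg: TrainConfig, dataset_root=None, pairs: list[SamplePair] | None = None,
          out_dir=None) -> tuple[Path | None, TrainState]:
    """Train a model; returns (best checkpoint path, training state)."""
    cfg.validate()
    if pairs is None:
        if dataset_root is None:
            raise ConfigurationError("train() needs a dataset_root or explicit pairs")
        pairs = scan_dataset(dataset_root)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
    if n_val >= len(pairs):
        raise ConfigurationError("validation carve-out would consume every pair")
    order = rng.permutation(len(pairs))
    val_pairs = [pairs[i] for i in order[:n_val]]
    train_pairs = [pairs[i] for i in order[n_val:]]

    loaded = [load_sample(p, cfg.image_size) for p in train_pairs]
    train_x = np.stack([im for im, _ in loaded])
    train_y = np.stack([mk for _, mk in loaded])
    loaded = [load_sample(p, cfg.image_size) for p in val_pairs]
    val_x = np.stack([im for im, _ in loaded])
    val_y = np.stack([mk for _, mk in loaded])

    nn.manual_seed(cfg.seed)
    model = CANet(cfg.model)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    policy = cfg.augmentation
    stopper = EarlyStopper(cfg.patience, cfg.min_delta)
    state = TrainState()
    best_path = out_dir / "best.npz" if out_dir is not None else None
    best_state_mem: dict | None = None

    t0 = time.time()
    for epoch in range(1, cfg.epochs + 1):
        idx = rng.permutation(len(train_x))
        losses = []
        for step, lo in enumerate(range(0, len(idx), cfg.batch_size)):
            sel = idx[lo:lo + cfg.batch_size]
            xb, yb = train_x[sel], train_y[sel]
            if policy is not None:
                aug = [augment(x, y, policy) for x, y in zip(xb, yb)]
                xb = np.stack([a for a, _ in aug])
                yb = np.stack([b for _, b in aug])
            model.zero_grad()
            logits = model(Tensor(xb))
            loss = total_loss(yb, logits, cfg.loss_smooth_eps)
            value = loss.total.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, step {step}"
                )
            loss.total.backward()
            opt.step()
            losses.append(value)
        val_mdsc, val_miou = _validation_scores(model, val_x, val_y, cfg.threshold)
        state.epoch = epoch
        state.history.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "val_mdsc": val_mdsc, "val_miou": val_miou,
        })
        improved = val_mdsc > state.best_val_mdsc + cfg.min_delta
        stop = stopper.update(val_mdsc)
        state.epochs_since_improvement = stopper.since_improvement
        if improved:
            state.best_val_mdsc = val_mdsc
            if best_path is not None:
                save_checkpoint(best_path, model, cfg)
            else:
                best_state_mem = model.state_dict()
        logger.info(
            "epoch %d | train loss %.4f | val mDSC %.4f | val mIoU %.4f | %.1fs",
            epoch, np.mean(losses), val_mdsc, val_miou, time.time() - t0,
        )
        if stop:
            logger.info("early stopping at epoch %d (patience %d)", epoch, cfg.patience)
            break
    if best_path is None and best_state_mem is not None:
        model.load_state_dict(best_state_mem)
        model.eval()
        state.model = model  # type: ignore[attr-defined]
    return best_path, state


# ---------------------------------------------------------------------------
# evaluation / prediction / ablations
# ---------------------------------------------------------------------------

def evaluate_model(model: CANet, pairs, image_size=(256, 256),
                   threshold: float = 0.5) -> MetricReport:
    loaded = [load_sample(p, image_size) for p in pairs]
    images = np.stack([im for im, _ in loaded])
    masks = [mk for _, mk in loaded]
    model.eval()
    probs = _forward_probs(model, images)
    return evaluate_dataset(list(zip(probs, masks)), threshold,
                            ids=[p.id for p in pairs])


def evaluate_checkpoint(checkpoint, dataset_root, threshold=None) -> MetricReport:
    model, meta = load_checkpoint(checkpoint)
    pairs = scan_dataset(dataset_root)
    return evaluate_model(model, pairs, tuple(meta["image_size"]),
                          threshold if threshold is not None else meta["threshold"])


def predict(checkpoint, image_dir, out_dir, threshold: float = 0.5) -> list[Path]:
    """Write a binary mask PNG and an 8-bit probability map per input image."""
    model, meta = load_checkpoint(checkpoint)
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = meta["image_size"]
    written = []
    files = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    for f in files:
        img = Image.open(f).convert("RGB").resize((w, h), Image.BILINEAR)
        x = (np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0 - 0.5) / 0.5
        prob = model.predict_proba(Tensor(x[None])).data[0, 0]
        mask = binarize(prob, threshold) * 255
        mask_path = out_dir / f"{f.stem}_mask.png"
        prob_path = out_dir / f"{f.stem}_prob.png"
        Image.fromarray(mask.astype(np.uint8)).save(mask_path)
        Image.fromarray((prob * 255).round().astype(np.uint8)).save(prob_path)
        written += [mask_path, prob_path]
    return written


ABLATION_COLUMNS = ("mIoU", "mDSC", "Recall", "Prec.", "F2", "HD")


def default_ablation_grid(baseline_family: str = "resnet50",
                          full_family: str = "pvt") -> list[tuple[str, str, set]]:
    """Six-row grid: baseline, backbone swap, one module at a time, full model."""
    return [
        (f"Baseline ({baseline_family})", baseline_family, set()),
        (f"{baseline_family}->{full_family}", full_family, set()),
        (f"{full_family} + RFM", full_family, {"rfm"}),
        (f"{full_family} + MCAM", full_family, {"mcam"}),
        (f"{full_family} + CAM", full_family, {"cam"}),
        ("Full model", full_family, {"rfm", "mcam", "cam"}),
    ]


def run_ablation(grid, cfg: TrainConfig, dataset_root=None, pairs=None,
                 test_fraction: float = 0.2, out_dir=None) -> pd.DataFrame:
    """Train/evaluate every grid row with a shared seed; one table out."""
    from .backbone import BackboneSpec, DEFAULT_CHANNELS

    if pairs is None:
        pairs = scan_dataset(dataset_root)
    n_train = len(pairs) - max(1, int(round(test_fraction * len(pairs))))
    from .data import split_train_test

    train_pairs, test_pairs = split_train_test(pairs, n_train, cfg.seed)
    rows = {}
    for name, family, modules in grid:
        row_cfg = replace(cfg)
        row_cfg.model = replace(
            cfg.model,
            backbone=BackboneSpec(family=family,
                                  channels=DEFAULT_CHANNELS.get(family)),
            use_cam="cam" in modules, use_mcam="mcam" in modules,
            use_rfm="rfm" in modules,
        )
        _, state = train(row_cfg, pairs=train_pairs)
        model = getattr(state, "model", None)
        if model is None:  # pragma: no cover - defensive
            raise RuntimeError("in-memory training did not retain a model")
        report = evaluate_model(model, test_pairs, row_cfg.image_size,
                                row_cfg.threshold)
        rows[name] = report.table_row()
        logger.info("ablation row %-24s mDSC %.4f", name, report.means["dsc"])
    table = pd.DataFrame.from_dict(rows, orient="index")[list(ABLATION_COLUMNS)]
    table.index.name = "Method"
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "ablation.csv")
    return table
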