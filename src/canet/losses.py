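"""Hybrid segmentation objective: binary cross-entropy + soft Dice.

    L_total = L_BCE + L_Dice

BCE is the pixel-mean cross-entropy computed in logit space (never forming
log p directly).  The Dice term uses soft probabilities, is computed per
image and averaged over the batch, with a small smoothing constant so empty
masks are well defined:

    L_Dice = 1 - (2 sum(y p) + eps) / (sum(y) + sum(p) + eps)

The sum is unweighted: both terms enter with coefficient one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, functional as F

DEFAULT_SMOOTH_EPS = 1e-6


@dataclass
class LossValue:
    total: Tensor
    bce: Tensor
    dice: Tensor

    def item(self) -> float:
        return self.total.item()


def _check_targets(y: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    y = np.asarray(y, dtype=np.float32)
    if y.shape != shape:
        raise ValueError(f"target shape {y.shape} does not match prediction {shape}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("targets must be binary {0, 1}")
    return y


def bce_loss(y: np.ndarray, p_logits: Tensor) -> Tensor:
    """Mean binary cross-entropy over all pixels, from logits."""
    y = _check_targets(y, p_logits.shape)
    return F.bce_with_logits(p_logits, y)


def dice_loss(y: np.ndarray, p: Tensor, smooth_eps: float = DEFAULT_SMOOTH_EPS) -> Tensor:
    """Soft Dice loss, per image then batch-averaged; `p` are probabilities."""
    y = np.asarray(y, dtype=np.float32)
    if y.shape != p.shape:
        raise ValueError(f"target shape {y.shape} does not match prediction {p.shape}")
    axes = tuple(range(1, p.ndim))
    yt = Tensor(y)
    inter = (yt * p).sum(axis=axes)
    denom = yt.sum(axis=axes) + p.sum(axis=axes)
    dice = (2.0 * inter + smooth_eps) / (denom + smooth_eps)
    return (1.0 - dice).mean()


def total_loss(y: np.ndarray, p_logits: Tensor,
               smooth_eps: float = DEFAULT_SMOOTH_EPS) -> LossValue:
    """Hybrid loss; reports the two components alongside their sum."""
    bce = bce_loss(y, p_logits)
    dice = dice_loss(y, p_logits.sigmoid(), smooth_eps)
    return LossValue(total=bce + dice, bce=bce, dice=dice)
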