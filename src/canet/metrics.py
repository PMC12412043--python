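"""Six-metric evaluation suite for binary segmentation.

Per image: IoU (Jaccard), Dice similarity coefficient, recall, precision,
F2 (F-beta with beta=2, weighting recall over precision — small lesions are
costlier to miss than to over-segment) and the exact symmetric Hausdorff
distance between foreground pixel sets, in pixels.  Dataset scores are
arithmetic means of the per-image values (never global pixel pooling).

Edge conventions (documented, exercised in tests):

* both masks empty      -> IoU = DSC = precision = recall = F2 = 1, HD = 0
* exactly one empty     -> ratios 0, HD = image diagonal (max possible pixel
  distance, sqrt((H-1)^2 + (W-1)^2))
* zero denominators in precision/recall/F2 otherwise -> 0
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .nn import Tensor

F_BETA = 2.0
METRIC_COLUMNS = ("iou", "dsc", "recall", "precision", "f2", "hd")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def binarize(p, threshold: float = 0.5) -> np.ndarray:
    """Probability map -> binary mask; a pixel is foreground iff p > threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    return (_as_array(p) > threshold).astype(np.uint8)


def _check_pair(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    pred, gt = _as_array(pred), _as_array(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    pred, gt = _check_pair(pred, gt)
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def iou_dsc(pred, gt) -> tuple[float, float]:
    pred, gt = _check_pair(pred, gt)
    inter = int(np.sum(pred & gt))
    union = int(np.sum(pred | gt))
    if union == 0:
        return 1.0, 1.0
    size_sum = int(pred.sum()) + int(gt.sum())
    return inter / union, 2.0 * inter / size_sum


def precision_recall_f2(pred, gt) -> tuple[float, float, float]:
    c = confusion_counts(pred, gt)
    if c.tp + c.fp + c.fn == 0:  # both masks empty
        return 1.0, 1.0, 1.0
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    b2 = F_BETA**2
    denom = b2 * precision + recall
    f2 = (1 + b2) * precision * recall / denom if denom else 0.0
    return precision, recall, f2


def hausdorff(pred, gt) -> float:
    """Exact symmetric Hausdorff distance between foreground pixel sets."""
    pred, gt = _check_pair(pred, gt)
    a = np.argwhere(pred.squeeze())
    b = np.argwhere(gt.squeeze())
    if a.size == 0 and b.size == 0:
        return 0.0
    if a.size == 0 or b.size == 0:
        h, w = pred.squeeze().shape[-2:]
        return float(np.hypot(h - 1, w - 1))
    d_ab = directed_hausdorff(a, b)[0]
    d_ba = directed_hausdorff(b, a)[0]
    return float(max(d_ab, d_ba))


def per_image_metrics(pred, gt) -> dict[str, float]:
    iou, dsc = iou_dsc(pred, gt)
    precision, recall, f2 = precision_recall_f2(pred, gt)
    return {
        "iou": iou, "dsc": dsc, "recall": recall, "precision": precision,
        "f2": f2, "hd": hausdorff(pred, gt),
    }


@dataclass
class MetricReport:
    per_image: pd.DataFrame  # one row per image: id + the six metrics
    means: dict[str, float]
    n_images: int

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"n_images": self.n_images, "means": self.means}, fh, indent=2)

    def table_row(self) -> dict[str, float]:
        """Means under their conventional table headings."""
        m = self.means
        return {"mIoU": m["iou"], "mDSC": m["dsc"], "Recall": m["recall"],
                "Prec.": m["precision"], "F2": m["f2"], "HD": m["hd"]}


def evaluate_dataset(pairs, threshold: float = 0.5, ids=None) -> MetricReport:
    """Per-image metrics + dataset means over (probability map, mask) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (prediction, mask) pair")
    if ids is None:
        ids = [f"img_{i:04d}" for i in range(len(pairs))]
    rows = []
    for img_id, (prob, gt) in zip(ids, pairs):
        pred = binarize(prob, threshold)
        rows.append({"id": img_id, **per_image_metrics(pred, _as_array(gt))})
    df = pd.DataFrame(rows)
    means = {c: float(df[c].mean()) for c in METRIC_COLUMNS}
    return MetricReport(per_image=df, means=means, n_images=len(df))
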