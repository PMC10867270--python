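"""Loss and evaluation metrics for binary ridge segmentation.

The loss is the standard multinomial cross-entropy on per-pixel score
vectors, ``loss(x, c) = -x[c] + log(sum_j exp(x[j]))``, averaged over all
pixels and evaluated with the log-sum-exp shift. Quality is reported as
pixel accuracy, precision, recall and intersection-over-union derived from
per-class confusion counts,

    Acc = (TP + TN) / (TP + TN + FP + FN) * 100
    Pr  = TP / (TP + FP) * 100
    Re  = TP / (TP + FN) * 100
    IoU = TP / (TP + FN + FP) * 100

with mIoU the mean IoU over the two classes. Dataset-level scores average
the per-image metrics by default (pooled pixel counts are available as an
option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Tensor
from .nn import functional as F

__all__ = ["ConfusionCounts", "ClassMetrics", "MetricReport",
           "cross_entropy_loss", "confusion_counts", "metrics_from_counts",
           "evaluate_dataset"]


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-pixel cross-entropy of raw class scores.

    Accepts a single score vector (K,) with a scalar label, one image
    (K, H, W) with labels (H, W), or a batch (N, K, H, W) with (N, H, W).
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.ndim == 1:
        logits = logits[None, :, None, None]
        labels = labels.reshape(1, 1, 1)
    elif logits.ndim == 3:
        logits = logits[None]
        labels = labels[None]
    elif logits.ndim != 4:
        raise ValueError(f"logits must be (K,), (K,H,W) or (N,K,H,W); got {logits.shape}")
    return float(F.cross_entropy_with_logits(Tensor(logits), labels.astype(np.intp)).item())


@dataclass
class ConfusionCounts:
    """Pixel tallies of the four prediction outcomes for one positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     positive_class: int = 1) -> ConfusionCounts:
    """Exact confusion tallies between two label masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} contains labels outside {{0, 1}}: {sorted(bad)}")
    p = pred == positive_class
    t = truth == positive_class
    return ConfusionCounts(tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
                           fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)))


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, iou) as percentages.

    Empty-class policy: when the class neither occurs nor is predicted
    (tp+fp+fn = 0) its precision, recall and IoU are 100% — the class is
    perfectly absent. A zero denominator with disagreement present (e.g. no
    predictions but positives exist) scores 0%. Metrics never raise.
    """
    if c.total == 0:
        raise ValueError("metrics require at least one evaluated pixel")
    acc = 100.0 * (c.tp + c.tn) / c.total
    if c.tp + c.fp + c.fn == 0:
        return acc, 100.0, 100.0, 100.0
    pr = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    re = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    iou = 100.0 * c.tp / (c.tp + c.fn + c.fp)
    return acc, pr, re, iou


@dataclass
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    iou: float


@dataclass
class MetricReport:
    """Dataset-level segmentation scores (percentages)."""

    per_class: dict[int, ClassMetrics]
    miou: float
    aggregation: str
    n_images: int
    per_image: pd.DataFrame = field(repr=False, default=None)

    @property
    def accuracy(self) -> float:
        return self.per_class[1].accuracy

    def to_frame(self) -> pd.DataFrame:
        """Per-image rows plus an aggregate row, machine-readable."""
        agg = {"image": "aggregate"}
        for cls, m in self.per_class.items():
            agg.update({f"acc_{cls}": m.accuracy, f"pr_{cls}": m.precision,
                        f"re_{cls}": m.recall, f"iou_{cls}": m.iou})
        agg["miou"] = self.miou
        rows = self.per_image if self.per_image is not None else pd.DataFrame()
        return pd.concat([rows, pd.DataFrame([agg])], ignore_index=True)

    def summary(self) -> str:
        lines = [f"{self.aggregation} over {self.n_images} image(s)"]
        for cls, m in self.per_class.items():
            name = "ridge" if cls == 1 else "background"
            lines.append(f"  class {cls} ({name}): Acc {m.accuracy:.1f}%  "
                         f"Pr {m.precision:.1f}%  Re {m.recall:.1f}%  IoU {m.iou:.1f}%")
        lines.append(f"  mIoU {self.miou:.1f}%")
        return "\n".join(lines)


def _image_metrics(pred: np.ndarray, truth: np.ndarray,
                   classes=(0, 1)) -> dict[int, tuple[ConfusionCounts, tuple]]:
    out = {}
    for cls in classes:
        c = confusion_counts(pred, truth, positive_class=cls)
        out[cls] = (c, metrics_from_counts(c))
    return out


def evaluate_dataset(model, dataset, aggregation: str = "per_image_mean",
                     split: str = "val") -> MetricReport:
    """Score a predictor over a dataset.

    ``model`` is anything with a ``predict(image) -> mask`` method;
    ``dataset`` is a :class:`~ridgeseg.synthetic.DatasetIndex` (the given
    split is used) or a list of (image, truth-mask) pairs. The default
    aggregation averages per-image metrics; ``pooled`` sums pixel counts
    over the whole set first.
    """
    if aggregation not in ("per_image_mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    pairs = dataset.load_pairs(split) if hasattr(dataset, "load_pairs") else list(dataset)
    if not pairs:
        raise ValueError("cannot evaluate an empty dataset")

    rows = []
    pooled = {0: ConfusionCounts(), 1: ConfusionCounts()}
    for i, (img, truth) in enumerate(pairs):
        pred = model.predict(img)
        per_cls = _image_metrics(pred, truth)
        row = {"image": i}
        for cls, (cnt, (acc, pr, re, iou)) in per_cls.items():
            pooled[cls] = pooled[cls] + cnt
            row.update({f"acc_{cls}": acc, f"pr_{cls}": pr,
                        f"re_{cls}": re, f"iou_{cls}": iou})
        row["miou"] = (per_cls[0][1][3] + per_cls[1][1][3]) / 2.0
        rows.append(row)
    frame = pd.DataFrame(rows)

    per_class = {}
    if aggregation == "per_image_mean":
        for cls in (0, 1):
            per_class[cls] = ClassMetrics(
                accuracy=float(frame[f"acc_{cls}"].mean()),
                precision=float(frame[f"pr_{cls}"].mean()),
                recall=float(frame[f"re_{cls}"].mean()),
                iou=float(frame[f"iou_{cls}"].mean()))
        miou = float(frame["miou"].mean())
    else:
        for cls in (0, 1):
            acc, pr, re, iou = metrics_from_counts(pooled[cls])
            per_class[cls] = ClassMetrics(acc, pr, re, iou)
        miou = (per_class[0].iou + per_class[1].iou) / 2.0
    return MetricReport(per_class=per_class, miou=miou, aggregation=aggregation,
                        n_images=len(pairs), per_image=frame)
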