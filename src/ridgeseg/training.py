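"""Training protocol: plain SGD on cross-entropy with per-epoch history.

Defaults follow the study protocol — SGD with learning rate 0.01, batch
size 4, 100 epochs, 512x512 inputs — with no schedule, momentum, weight
decay or augmentation unless explicitly configured. After every epoch the
model is scored on the validation split; the "best" checkpoint is the one
with the highest validation mIoU.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import evaluate_dataset
from .model import ASPNet
from .nn import SGD
from .nn import functional as F
from .nn.tensor import Tensor

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EpochRecord", "TrainHistory", "train",
           "plot_training_curves"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 4
    epochs: int = 100
    input_size: int = 512
    seed: int = 0
    checkpoint_dir: Path | None = None
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["checkpoint_dir"] = str(self.checkpoint_dir) if self.checkpoint_dir else None
        return d


@dataclass
class EpochRecord:
    epoch: int            # 1-based
    train_loss: float     # mean over the epoch's batches
    val_accuracy: float   # percent
    val_miou: float       # percent


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based epoch with the highest validation mIoU."""
        if not self.records:
            raise ValueError("history is empty")
        return max(self.records, key=lambda r: r.val_miou).epoch

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def save(self, path: Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: Path) -> "TrainHistory":
        frame = pd.read_csv(path)
        return cls([EpochRecord(int(r.epoch), float(r.train_loss),
                                float(r.val_accuracy), float(r.val_miou))
                    for r in frame.itertuples()])


def _to_batch_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([p[0] for p in pairs]).astype(np.float32) / 255.0
    masks = np.stack([p[1] for p in pairs]).astype(np.intp)
    return np.ascontiguousarray(imgs.transpose(0, 3, 1, 2)), masks


def train(model: ASPNet, dataset, cfg: TrainConfig) -> tuple[ASPNet, TrainHistory]:
    """Train ``model`` on a dataset's train split; validate per epoch.

    ``dataset`` is a :class:`~ridgeseg.synthetic.DatasetIndex` or any object
    with ``load_pairs(split)``. Deterministic for a fixed ``cfg.seed``: the
    shuffling stream and every update are reproducible. Raises
    ``RuntimeError`` naming the epoch and batch if the loss goes non-finite.
    """
    train_pairs = dataset.load_pairs("train")
    val_pairs = dataset.load_pairs("val")
    if not train_pairs or not val_pairs:
        raise ValueError("dataset must have non-empty train and val splits")

    x_all, y_all = _to_batch_arrays(train_pairs)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.learning_rate,
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    best_miou = -1.0

    n = len(train_pairs)
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.perf_counter()
        model.train()
        order = rng.permutation(n)
        losses = []
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(x_all[idx])
            loss = F.cross_entropy_with_logits(model.forward(x), y_all[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        report = evaluate_dataset(model, val_pairs, aggregation="per_image_mean")
        rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                          val_accuracy=report.accuracy, val_miou=report.miou)
        history.records.append(rec)
        logger.info("epoch %d/%d: loss %.4f, val acc %.2f%%, val mIoU %.2f%% (%.1fs)",
                    epoch, cfg.epochs, rec.train_loss, rec.val_accuracy,
                    rec.val_miou, time.perf_counter() - t0)
        if ckpt_dir:
            model.save_checkpoint(ckpt_dir / "last.npz")
            if rec.val_miou > best_miou:
                model.save_checkpoint(ckpt_dir / "best.npz")
            history.save(ckpt_dir / "history.csv")
        best_miou = max(best_miou, rec.val_miou)
    return model, history


def plot_training_curves(history: TrainHistory, out_dir: Path) -> tuple[Path, Path]:
    """Write loss-vs-epoch and validation-accuracy-vs-epoch curves as PNGs."""
    if not history.records:
        raise ValueError("cannot plot an empty history")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = history.to_frame()
    paths = []
    for col, ylabel, fname in (("train_loss", "training loss", "loss_curve.png"),
                               ("val_accuracy", "validation accuracy (%)",
                                "accuracy_curve.png")):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(frame["epoch"], frame[col], marker="o", ms=3)
        ax.set_xlabel("epoch")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        p = out_dir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return tuple(paths)
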