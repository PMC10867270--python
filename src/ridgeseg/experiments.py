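"""Desk-scale experiment presets.

The full protocol (base 64 channels, 512x512 tiles, 600-tile dataset, 100
epochs) is too heavy for a laptop-class run, so the package defines one
fixed reduced configuration used by its own verification experiments: the
same architecture at base 16 channels on 64x64 tiles, a 36-tile dataset
split 5:1, SGD with learning rate 0.01 and batch size 4. The easy-scene
learning check trains 20 epochs; the vacancy-robustness check keeps the
full 100-epoch protocol because discriminating speckle distractors from
ridges converges more slowly than the clean-stripe task. Tiled inference
on large scenes uses tiles of the network's training input size.

These functions are the single source of truth for those conditions; the
test suite and the reproduction script both call them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import confusion_counts, metrics_from_counts
from .model import ASPNet, ModelConfig
from .synthetic import DatasetIndex, SceneSpec, generate_dataset, generate_large_scene, render_scene
from .tiling import segment_large
from .training import TrainConfig, TrainHistory, train

__all__ = ["REDUCED_TILE", "REDUCED_BASE_CHANNELS", "EASY_EPOCHS", "HARD_EPOCHS",
           "reduced_scene_spec", "make_reduced_dataset", "train_reduced",
           "large_scene_miou", "vacancy_ridge_percent"]

REDUCED_TILE = 64           # tile side, pixels
REDUCED_BASE_CHANNELS = 16
REDUCED_N_TILES = 36        # 30 train / 6 val at 5:1
EASY_EPOCHS = 20
HARD_EPOCHS = 100
LARGE_SCENE_SIDE = 1024


def reduced_scene_spec(difficulty: str, seed: int) -> SceneSpec:
    """The 64x64 scene conditions: two ridges of width 5-12 px."""
    return SceneSpec.preset(difficulty, height=REDUCED_TILE, width=REDUCED_TILE,
                            n_ridges=2, ridge_width_range=(5, 12), seed=seed)


def make_reduced_dataset(root: Path, difficulty: str, seed: int,
                         n_tiles: int = REDUCED_N_TILES) -> DatasetIndex:
    return generate_dataset(n_tiles, (5, 1), root,
                            reduced_scene_spec(difficulty, seed))


def train_reduced(dataset: DatasetIndex, seed: int,
                  epochs: int) -> tuple[ASPNet, TrainHistory]:
    """Train the base-16 network with the standard optimiser settings."""
    model = ASPNet(ModelConfig(base_channels=REDUCED_BASE_CHANNELS, seed=seed))
    cfg = TrainConfig(learning_rate=0.01, batch_size=4, epochs=epochs,
                      input_size=REDUCED_TILE, seed=seed)
    return train(model, dataset, cfg)


def large_scene_miou(model: ASPNet, spec: SceneSpec,
                     side: int = LARGE_SCENE_SIDE,
                     tile_size: int = REDUCED_TILE) -> float:
    """mIoU of tiled inference on one freshly rendered large scene."""
    img, truth = generate_large_scene(side, side, spec)
    pred = segment_large(img, model, tile_size=tile_size)
    ious = [metrics_from_counts(confusion_counts(pred, truth, c))[3] for c in (0, 1)]
    return float(np.mean(ious))


def vacancy_ridge_percent(model: ASPNet, spec: SceneSpec,
                          seeds: range) -> float:
    """Percentage of vacancy-distractor pixels the model labels as ridge.

    Rendered scenes at the given seeds are pooled; the rate is
    100 * (#vacancy pixels predicted ridge) / (#vacancy pixels).
    """
    vac_total = leaked = 0
    for s in seeds:
        sc = render_scene(spec.replace(seed=int(s)))
        pred = model.predict(sc.image)
        vac_total += int(sc.vacancy_mask.sum())
        leaked += int((pred[sc.vacancy_mask] == 1).sum())
    if vac_total == 0:
        raise ValueError("no vacancy pixels rendered; use a hard-difficulty spec")
    return 100.0 * leaked / vac_total
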