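"""Shared fixtures.

The two trained-model fixtures reproduce the package's reduced study
conditions (see ridgeseg.experiments) once per session; several acceptance
properties share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ridgeseg import experiments
from ridgeseg.model import ASPNet, ModelConfig
from ridgeseg.synthetic import SceneSpec

MASTER_SEED = 1


@pytest.fixture(scope="session")
def tiny_model() -> ASPNet:
    """A desk-sized network for shape/gradient tests (base 4 channels)."""
    return ASPNet(ModelConfig(base_channels=4, seed=0))


@pytest.fixture(scope="session")
def tiny_spec() -> SceneSpec:
    return SceneSpec.preset("easy", height=16, width=16, n_ridges=1,
                            ridge_width_range=(3, 5), seed=3)


@pytest.fixture(scope="session")
def easy_run(tmp_path_factory):
    """Reduced model trained on the easy 64x64 condition (20 epochs)."""
    root = tmp_path_factory.mktemp("easy_data")
    dataset = experiments.make_reduced_dataset(root, "easy", seed=41 + MASTER_SEED)
    model, history = experiments.train_reduced(dataset, seed=MASTER_SEED,
                                               epochs=experiments.EASY_EPOCHS)
    return {"model": model, "history": history, "dataset": dataset,
            "spec": experiments.reduced_scene_spec("easy", 41 + MASTER_SEED)}


@pytest.fixture(scope="session")
def hard_run(tmp_path_factory):
    """Reduced model trained on the hard (vacancy-distractor) condition."""
    root = tmp_path_factory.mktemp("hard_data")
    dataset = experiments.make_reduced_dataset(root, "hard", seed=41 + MASTER_SEED)
    model, history = experiments.train_reduced(dataset, seed=MASTER_SEED,
                                               epochs=experiments.HARD_EPOCHS)
    return {"model": model, "history": history, "dataset": dataset,
            "spec": experiments.reduced_scene_spec("hard", 41 + MASTER_SEED)}


def rand_image(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
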