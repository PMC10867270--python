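"""Unified run configuration: defaults < config file < CLI flags.

A single YAML file holds ``scene``, ``model``, ``train`` and ``paths``
sections mirroring :class:`~ridgeseg.synthetic.SceneSpec`,
:class:`~ridgeseg.model.ModelConfig` and
:class:`~ridgeseg.training.TrainConfig`. Loading merges the file over the
dataclass defaults; explicit overrides (dotted keys, e.g. ``train.epochs``)
merge last. A loaded config re-saves to an identical structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic import SceneSpec
from .training import TrainConfig

__all__ = ["RunConfig", "setup_logging"]


def _tuplify(cls, d: dict) -> dict:
    """YAML round-trips tuples as lists; coerce back per dataclass field."""
    out = dict(d)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


@dataclass
class RunConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    paths: dict = field(default_factory=lambda: {
        "data_dir": "data", "checkpoint_dir": "checkpoints", "output_dir": "out"})
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {"scene": self.scene.to_dict(), "model": self.model.to_dict(),
                "train": self.train.to_dict(), "paths": dict(self.paths),
                "log_level": self.log_level}

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        """Build a config from defaults, an optional file, and dotted overrides."""
        data = cls().to_dict()
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            for section, vals in loaded.items():
                if section not in data:
                    raise ValueError(f"unknown config section {section!r}")
                if isinstance(vals, dict):
                    unknown = set(vals) - set(data[section])
                    if unknown:
                        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
                    data[section].update(vals)
                else:
                    data[section] = vals
        for key, value in (overrides or {}).items():
            if value is None:
                continue
            section, _, name = key.partition(".")
            if name:
                data[section][name] = value
            else:
                data[section] = value
        tc = dict(data["train"])
        if tc.get("checkpoint_dir"):
            tc["checkpoint_dir"] = Path(tc["checkpoint_dir"])
        return cls(scene=SceneSpec(**_tuplify(SceneSpec, data["scene"])),
                   model=ModelConfig(**_tuplify(ModelConfig, data["model"])),
                   train=TrainConfig(**_tuplify(TrainConfig, tc)),
                   paths=data["paths"], log_level=data["log_level"])


def setup_logging(level: str = "INFO", log_file=None) -> None:
    """Timestamped, leveled logging to stderr plus an optional file."""
    import logging
    import sys

    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True)
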