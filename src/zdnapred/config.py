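"""Run configuration: YAML schema, defaults and provenance snapshots.

Defaults are the operating point of the published annotation recipe:
5000-nt windows, 3:1 background windows, 4:1 stratified train/test split,
5 folds, dropout 0.5, region rules join<11 / keep>=11 / combine<10, and a
default probability cutoff of 0.343 (``auto`` re-derives the F1-optimal
cutoff from the data at hand). Every run writes a resolved-config copy
next to its outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model_zoo import (
    BEST_CNN_SPEC,
    BEST_RNN_SPEC,
    INTERPRETATION_CNN_SPEC,
    ModelSpec,
    TrainOptions,
)

__all__ = ["RunConfig", "ConfigError", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.343

_PRESETS = {
    "best_cnn": BEST_CNN_SPEC,
    "best_rnn": BEST_RNN_SPEC,
    "interpretation_cnn": INTERPRETATION_CNN_SPEC,
}


class ConfigError(ValueError):
    pass


@dataclass
class PathsConfig:
    genome: str | None = None
    labels: str | None = None
    manifest: str | None = None
    blacklist: str | None = None
    output_dir: str = "zdnapred_out"


@dataclass
class DatasetConfig:
    window_length: int = 5000
    background_ratio: int = 3
    train_fraction: float = 0.8
    folds: int = 5


@dataclass
class AnnotationConfig:
    threshold: float | str = DEFAULT_THRESHOLD  # or "auto"
    join_gap: int = 11
    min_length: int = 11
    combine_proximity: int = 10


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    model: dict | str = "best_cnn"
    training: dict = field(default_factory=dict)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    # -- parsing -------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config root must be a mapping")
        known = {"paths", "dataset", "model", "training", "annotation", "seed"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(
                paths=PathsConfig(**doc.get("paths", {})),
                dataset=DatasetConfig(**doc.get("dataset", {})),
                model=doc.get("model", "best_cnn"),
                training=dict(doc.get("training", {})),
                annotation=AnnotationConfig(**doc.get("annotation", {})),
                seed=int(doc.get("seed", 0)),
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                doc = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"invalid YAML: {exc}") from exc
        return cls.from_dict(doc)

    def validate(self) -> None:
        d = self.dataset
        if d.window_length < 1:
            raise ConfigError("window_length must be >= 1")
        if d.background_ratio < 0:
            raise ConfigError("background_ratio must be >= 0")
        if not 0.0 < d.train_fraction <= 1.0:
            raise ConfigError("train_fraction must be in (0, 1]")
        if d.folds < 2:
            raise ConfigError("folds must be >= 2")
        a = self.annotation
        if isinstance(a.threshold, str):
            if a.threshold != "auto":
                raise ConfigError("threshold must be a number or 'auto'")
        elif not 0.0 <= float(a.threshold) <= 1.0:
            raise ConfigError("threshold must be in [0, 1]")
        if isinstance(self.model, str) and self.model not in _PRESETS:
            raise ConfigError(
                f"unknown model preset {self.model!r}; options: {sorted(_PRESETS)}"
            )
        try:
            TrainOptions(**self.training)
        except TypeError as exc:
            raise ConfigError(f"invalid training options: {exc}") from exc
        self.model_spec()  # validates inline block lists

    # -- accessors -----------------------------------------------------

    def model_spec(self) -> ModelSpec:
        if isinstance(self.model, str):
            return _PRESETS[self.model]
        try:
            return ModelSpec.from_dict(self.model)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid model spec: {exc}") from exc

    def train_options(self) -> TrainOptions:
        return TrainOptions(**self.training)

    # -- provenance ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "paths": asdict(self.paths),
            "dataset": asdict(self.dataset),
            "model": self.model,
            "training": dict(self.training),
            "annotation": asdict(self.annotation),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write_resolved(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
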