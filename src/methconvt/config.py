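"""Run configuration: strict YAML schema over the per-stage dataclasses.

Unknown keys are rejected outright — a silently ignored typo in a tuning run
is worse than a crash — and every command writes its resolved configuration
and seed next to its outputs so any run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelSpec
from .synthetic import SyntheticConfig
from .training import LossConfig, TrainConfig

SCHEMA_VERSION = "1"

# ModelSpec fields that the pipeline itself derives from the data
_DERIVED_MODEL_FIELDS = {"P", "n_tissues"}


def _check_keys(mapping: dict, allowed: set[str], section: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _coerce_section(cls, mapping: dict, section: str) -> dict:
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(mapping, fields, section)
    return dict(mapping)


@dataclass
class RunConfig:
    synthetic: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)  # keys: k, fractions
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)  # keys: seeds, baselines
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        self.synthetic = _coerce_section(SyntheticConfig, self.synthetic, "synthetic")
        _check_keys(self.preprocess, {"k", "fractions"}, "preprocess")
        model_fields = {
            f.name for f in dataclasses.fields(ModelSpec)
        } - _DERIVED_MODEL_FIELDS
        _check_keys(self.model, model_fields, "model")
        self.train = _coerce_section(TrainConfig, self.train, "train")
        self.loss = _coerce_section(LossConfig, self.loss, "loss")
        _check_keys(self.evaluation, {"seeds", "baselines"}, "evaluation")

    # -- constructors --------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        _check_keys(
            raw,
            {"synthetic", "preprocess", "model", "train", "loss", "evaluation",
             "schema_version"},
            "root",
        )
        return cls(**raw)

    # -- materialized section objects ----------------------------------
    def synthetic_config(self, seed: int | None = None) -> SyntheticConfig:
        kw = dict(self.synthetic)
        if seed is not None:
            kw["seed"] = seed
        return SyntheticConfig(**kw)

    def train_config(self, seed: int | None = None) -> TrainConfig:
        kw = dict(self.train)
        if seed is not None:
            kw["seed"] = seed
        return TrainConfig(**kw)

    def loss_config(self) -> LossConfig:
        return LossConfig(**self.loss)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_provenance(out_dir: str | Path, cfg: RunConfig, seed: int | None,
                     command: str) -> None:
    """Write the resolved config and a run manifest next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": cfg.config_hash(),
        "schema_version": cfg.schema_version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
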