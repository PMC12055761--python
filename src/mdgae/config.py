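"""Structured run configuration.

A run is described by one YAML (or JSON) file with nested sections for the
NMF stage, the encoder, the decoders, training, and evaluation, plus a
global seed and output directory.  Unspecified fields take the default
hyperparameters (masking rate 0.4, loss weight 0.6, encoder dims [64, 128],
decoder dims [128, 64], learning rate 0.001, K=90, mu1=mu2=0.01); unknown
keys are rejected with the offending key named.

One global seed derives independent per-stage seeds (NMF initialization,
masking, negative sampling, parameter initialization) through the counter
scheme in :func:`mdgae.gae.derive_seed`, so each stage is reproducible in
isolation.  Explicit per-section seeds override the derivation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .gae import DecoderConfig, EncoderConfig, TrainingConfig, derive_seed
from .nmf import NMFConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unparseable files, unknown keys, or invalid values."""


class NMFSection(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    K: int = 90
    mu1: float = 0.01
    mu2: float = 0.01
    max_iterations: int = Field(default=500, ge=1)
    rel_tolerance: float = Field(default=1e-6, ge=0)
    eps_div: float = Field(default=1e-12, gt=0)
    seed: int | None = None
    weight_mode: str = "ones"


class EvaluationSection(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    k_folds: int = Field(default=5, ge=2)
    threshold: float = 0.5


class RunConfig(BaseModel):
    """Fully resolved configuration for one pipeline run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    nmf: NMFSection = NMFSection()
    encoder: EncoderConfig = EncoderConfig()
    decoder: DecoderConfig = DecoderConfig()
    training: TrainingConfig = TrainingConfig()
    evaluation: EvaluationSection = EvaluationSection()
    seed: int = 0
    output_dir: str = "runs"

    def nmf_config(self) -> NMFConfig:
        section = self.nmf.model_dump()
        if section["seed"] is None:
            section["seed"] = derive_seed(self.seed, "nmf")
        return NMFConfig(**section)

    def training_config(self) -> TrainingConfig:
        if "seed" in self.training.model_fields_set:
            return self.training
        return self.training.model_copy(update={"seed": self.seed})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: unparseable configuration: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration ({details})") from exc
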