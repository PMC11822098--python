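"""Schema-validated run configuration (YAML).

A single structured file holds every controller and peripheral hyperparameter,
the experiment sizes and the master seed.  Unknown keys are rejected and
validation errors name the offending key.  An empty file yields the full
default configuration, whose values were selected by the packaged grid search
(scripts/select_defaults.py).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .controller import ControllerParams
from .peripheral import PeripheralParams
from .stimuli import TYPE_IDS, AugmentParams


class ControllerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c: float = Field(default=ControllerParams.c, gt=0)
    r: float = Field(default=ControllerParams.r, ge=1)
    q: float = Field(default=ControllerParams.q, gt=0)
    t: float = ControllerParams.t
    u: float = ControllerParams.u
    d: float = ControllerParams.d
    gamma: float = ControllerParams.gamma
    attention_entropy_sign: float = ControllerParams.attention_entropy_sign
    recruit_threshold: float = Field(default=ControllerParams.recruit_threshold,
                                     ge=-1.0, le=1.01)
    lr_centers: float = Field(default=ControllerParams.lr_centers, ge=0)
    lr_attention: float = Field(default=ControllerParams.lr_attention, ge=0)
    lr_assoc: float = Field(default=ControllerParams.lr_assoc, ge=0)
    grad_clip: float = ControllerParams.grad_clip
    duplicate_center_guard: bool = ControllerParams.duplicate_center_guard

    def to_params(self) -> ControllerParams:
        return ControllerParams(**self.model_dump())


class PeripheralConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lam: float = Field(default=PeripheralParams.lam, gt=0)
    l1_weight: float = Field(default=PeripheralParams.l1_weight, ge=0)
    n_iterations: int = Field(default=PeripheralParams.n_iterations, ge=1)
    lr_g: float = Field(default=PeripheralParams.lr_g, ge=0)
    grad_clip: float = PeripheralParams.grad_clip
    zero_threshold: float = Field(default=PeripheralParams.zero_threshold, ge=0)
    finetune_lr: float = Field(default=PeripheralParams.finetune_lr, gt=0)
    finetune_epochs: int = Field(default=PeripheralParams.finetune_epochs, ge=0)
    finetune_patience: int = Field(default=PeripheralParams.finetune_patience, ge=1)
    finetune_batch_size: int = Field(default=PeripheralParams.finetune_batch_size, ge=1)
    finetune_val_fraction: float = Field(
        default=PeripheralParams.finetune_val_fraction, gt=0, lt=1)

    def to_params(self) -> PeripheralParams:
        return PeripheralParams(**self.model_dump())


class AugmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gain_range: float = Field(default=AugmentParams.gain_range, ge=0)
    block_gain_range: float = Field(default=AugmentParams.block_gain_range, ge=0)
    jitter_sd: float = Field(default=AugmentParams.jitter_sd, ge=0)

    def to_params(self) -> AugmentParams:
        return AugmentParams(**self.model_dump())


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    problem_types: list[str] = Field(default_factory=lambda: list(TYPE_IDS))
    variant: str = "M1"
    n_restarts: int = Field(default=100, ge=1)
    n_repetitions: int = Field(default=32, ge=1)
    master_seed: int = 0
    n_filters: int = Field(default=64, ge=3)
    n_augment: int = Field(default=1024, ge=1)

    @field_validator("problem_types")
    @classmethod
    def _known_types(cls, v: list[str]) -> list[str]:
        for tid in v:
            if tid not in TYPE_IDS:
                raise ValueError(f"problem_types: unknown type {tid!r}")
        return v

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v: str) -> str:
        if v not in ("M1", "M2", "M3", "M4"):
            raise ValueError(f"variant: unknown variant {v!r}")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    peripheral: PeripheralConfig = Field(default_factory=PeripheralConfig)
    augmentation: AugmentConfig = Field(default_factory=AugmentConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing/empty file parts use defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return RunConfig.model_validate(raw or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
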