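"""Run configuration: one YAML file drives the whole workflow.

Unknown keys are rejected (typos like ``lamda_pix`` fail loudly, naming the
offending key). A single top-level seed fans out to per-stage seeds by fixed
offsets so one knob controls reproducibility.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]

ConfigError = ValidationError

_SEED_OFFSETS = {"data": 11, "stage1": 23, "stage2": 37, "classifier": 53}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Strict):
    n_stained: int = Field(400, ge=0)
    n_unstained: int = Field(80, ge=0)
    paired: bool = False
    tile: int = Field(256, ge=8)
    density: float = Field(5.0, ge=0)
    n_classes: int = Field(4, ge=1)
    noise_sd: float = Field(0.02, ge=0)


class Stage1Config(_Strict):
    steps: int = Field(100, gt=0)
    batch_size: int = Field(2, gt=0)
    lr: float = Field(2e-4, gt=0)
    base_width: int = Field(8, gt=0)
    n_res_blocks: int = Field(3, gt=0)
    generator: str = "separable"
    lambda_cyc: float = Field(10.0, ge=0)
    lambda_dc: float = Field(1.0, ge=0)
    lambda_adv: float = Field(1.0, ge=0)
    buffer_capacity: int = Field(64, gt=0)


class Stage2Config(_Strict):
    steps: int = Field(300, gt=0)
    batch_size: int = Field(2, gt=0)
    lr: float = Field(2e-4, gt=0)
    critic_steps: int = Field(1, gt=0)
    feature_width: int = Field(32, gt=0)
    critic_width: int = Field(16, gt=0)
    generator: str = "pffn"
    adv_variant: str = "wgan_gp"
    lambda_gp: float = Field(10.0, ge=0)
    lambda_pix: float = Field(100.0, ge=0)
    lambda_fm: float = Field(10.0, ge=0)
    gamma_r1: float = Field(10.0, ge=0)


class EvalConfig(_Strict):
    feature_embedder: str = "pool8"
    use_classifier: bool = True
    classifier_epochs: int = Field(60, gt=0)


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/default"
    version: str = "1"
    data: DataConfig = Field(default_factory=DataConfig)
    stage1: Stage1Config = Field(default_factory=Stage1Config)
    stage2: Stage2Config = Field(default_factory=Stage2Config)
    evaluate: EvalConfig = Field(default_factory=EvalConfig)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _SEED_OFFSETS[stage]) % (2 ** 31)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
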