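"""Run configuration: a validated YAML/JSON file driving every command.

One global seed fans out deterministically to per-stage seeds (a CRC of the
stage name folded into the seed), so a single config + seed reproduces the
whole simulate -> featurize -> train -> evaluate chain bit for bit.
Backend selection and credentials live here, never on the command line.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class PathsConfig(BaseModel):
    cohort: str = "artifacts/cohort.jsonl"
    truth: str = "artifacts/truth.jsonl"
    features_dir: str = "artifacts/features"
    model: str = "artifacts/model.pkl"
    reports_dir: str = "artifacts/reports"


class CohortConfig(BaseModel):
    n_cases: int = Field(4526, ge=1)
    messiness: bool = True
    narrative_signal: bool = True


class FeaturesConfig(BaseModel):
    surgeon_config: str = "metrics"  # configuration 1 = "name", 2 = "metrics"
    min_count: int = Field(10, ge=1)
    log_target: bool = False
    text_mode: str = "structured"

    @field_validator("surgeon_config")
    @classmethod
    def _cfg(cls, v):
        if v not in ("metrics", "name"):
            raise ValueError("surgeon_config must be 'metrics' or 'name'")
        return v


class BackendConfig(BaseModel):
    kind: str = "offline"  # "offline" | "remote"
    endpoint: str = ""
    model: str = ""
    api_key_env: str = ""  # environment variable holding the credential


class ModelConfig(BaseModel):
    head_layers: tuple[int, ...] = (256, 128)
    dropout_rate: float = Field(0.3, ge=0, lt=1)
    fusion_units: int = Field(64, gt=0)
    learning_rate: float = Field(0.001, gt=0)
    max_epochs: int = Field(200, ge=1)
    batch_size: int = Field(32, ge=1)
    patience: int = Field(10, ge=1)


class EvaluationConfig(BaseModel):
    test_frac: float = Field(0.15, gt=0, lt=0.5)
    k: int = Field(5, ge=2)
    importance_repeats: int = Field(10, ge=1)


class RunConfig(BaseModel):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    structuring_backend: BackendConfig = Field(default_factory=BackendConfig)
    embedding_backend: BackendConfig = Field(default_factory=BackendConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config; None -> all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed ^ zlib.crc32(stage.encode())) % (2**31)
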