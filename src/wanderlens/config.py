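"""Run configuration: a validated YAML-backed schema for pipeline runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class MovementConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ts: float = Field(60.0, gt=0, description="segmentation gap threshold, s")
    dwell_min: float = Field(2.0, gt=0, description="stationarity dwell, s")
    theta_min: float = Field(90.0, gt=0, description="sharp-angle threshold, deg")
    turn_min: float = Field(30.0, gt=0, description="turn-marker threshold, deg")
    center_tol: float = Field(30.0, gt=0, description="center-ward cone half-angle, deg")
    v_cap: float = Field(3.0, gt=0, description="speed mapped to lightest shade, m/s")
    v_max: float = Field(15.0, gt=0, description="noise filter speed gate, m/s")
    d_max: float = Field(5.0, gt=0, description="noise filter distance gate, m")
    canvas_width: int = Field(130, gt=0)
    canvas_height: int = Field(100, gt=0)


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    K: int = Field(50, ge=2, description="visual vocabulary size")
    descriptor: str = Field("orb", description="keypoint descriptor kind")
    normalization: str = Field("l2", description="BoVW histogram norm: l2/l1/none")


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str = Field("svm", description="nb / knn / dt / svm / nn")
    use_smote: bool = True
    smote_k: int = Field(5, ge=1)
    refit_vocab_per_fold: bool = True


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    events_dir: str = ""
    position_table: str = ""
    manifest: str = ""
    out_dir: str = "out"
    seed: int = 0
    movement: MovementConfig = Field(default_factory=MovementConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, used as a provenance stamp."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
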