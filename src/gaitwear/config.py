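"""Pipeline configuration: validated sections with strict (unknown-key) parsing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessConfig(_Strict):
    posture_cutoff_hz: float = 0.5
    activity_band_hz: tuple[float, float] = (0.5, 11.0)
    gyro_cutoff_hz: float = 11.0
    baro_cutoff_hz: float = 0.5
    baro_median_window_s: float = 0.5
    order: int = 2


class WindowsConfig(_Strict):
    length: int = 128
    hop: int = 64


class FeaturesConfig(_Strict):
    standardize_per_subject: bool = True


class EvaluationConfig(_Strict):
    task: str = "gait"
    config_id: str = "A"
    model: str = "svm"
    grid: str = "reduced"  # "full" or "reduced" (first grid entry)


class SimulateConfig(_Strict):
    enabled: bool = True
    n_subjects: int = 6
    minutes: float = 6.0


class PathsConfig(_Strict):
    input_dir: str | None = None
    output_dir: str = "gaitwear_out"


class PipelineConfig(_Strict):
    seed: int = 20220926
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    windows: WindowsConfig = Field(default_factory=WindowsConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def stage_hash(self, *sections: str) -> str:
        """Content hash of configuration sections (plus the seed)."""
        payload = {"seed": self.seed}
        for s in sections:
            payload[s] = getattr(self, s).model_dump(mode="json")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
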