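"""Validated run configuration for the pipeline and CLI.

Every default equals the standard device setting where one exists: 50 kHz
sampling, 2500-sample frames, 12 800 Hz cut-off, 60 Hz physiological band
edge, and the 10/5/3 min heating protocol from 33 to 42 °C at 2 °C/min.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .spectral import DEFAULT_CUTOFF, DEFAULT_FRAME_LENGTH, DEFAULT_FS


class AcquisitionConfig(BaseModel):
    fs: float = DEFAULT_FS
    frame_length: int = DEFAULT_FRAME_LENGTH
    cutoff: float = DEFAULT_CUTOFF
    window: str = "rectangular"
    K: float = 1.0

    @field_validator("fs", "cutoff", "K")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @model_validator(mode="after")
    def _cutoff_below_nyquist(self) -> "AcquisitionConfig":
        if self.cutoff > self.fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff} Hz exceeds Nyquist {self.fs / 2} Hz"
            )
        return self

    @property
    def df(self) -> float:
        return self.fs / self.frame_length


class AnalysisConfig(BaseModel):
    band: tuple[float, float] = (60.0, DEFAULT_CUTOFF)
    f_start: float = 60.0
    curve_average: str = "curve-mean"

    @field_validator("band")
    @classmethod
    def _band_order(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not 0 <= v[0] < v[1]:
            raise ValueError(f"band limits out of order: {v}")
        return v

    @field_validator("curve_average")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("curve-mean", "spectrum-mean"):
            raise ValueError(f"unknown averaging mode {v!r}")
        return v


class StageConfig(BaseModel):
    name: str
    t_start: float
    t_end: float
    temperature: float
    ramp_rate: Optional[float] = None  # °C/min; a ramp towards `temperature`
    ramp_from: Optional[float] = None


class ProtocolConfig(BaseModel):
    stages: list[StageConfig] = Field(
        default_factory=lambda: [
            StageConfig(name="stage1", t_start=0.0, t_end=600.0, temperature=33.0),
            StageConfig(
                name="stage2", t_start=600.0, t_end=900.0,
                temperature=42.0, ramp_rate=2.0, ramp_from=33.0,
            ),
            StageConfig(name="stage3", t_start=900.0, t_end=1080.0, temperature=42.0),
        ]
    )


class ClassifyConfig(BaseModel):
    feature_sets: list[list[str]] = Field(
        default_factory=lambda: [
            ["dbp"], ["abc"], ["dv31"],
            ["dbp", "abc"], ["dbp", "dv31"], ["dbp", "abc", "dv31"],
        ]
    )
    fixture: str = "patients-vs-older"


class SimulateConfig(BaseModel):
    seed: int = 0
    n_per_group: int = 50
    plan_scale: float = 0.1
    archetype: str = "mixed"


class RunConfig(BaseModel):
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_plan(self):
        from .protocol import Stage, StagePlan, TemperatureRamp

        stages = []
        for s in self.protocol.stages:
            if s.ramp_rate is not None:
                temp = TemperatureRamp(
                    start=s.ramp_from if s.ramp_from is not None else s.temperature,
                    rate=s.ramp_rate,
                    target=s.temperature,
                )
            else:
                temp = s.temperature
            stages.append(Stage(s.name, s.t_start, s.t_end, temp))
        return StagePlan(stages=tuple(stages))


def load_config(path: str | None = None) -> RunConfig:
    """Configuration from a JSON file, or the defaults when `path` is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))
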