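"""Run configuration: a validated YAML-backed description of one analysis.

Every stage of the pipeline consumes only the config plus prior-stage
artifacts; all randomness flows from ``seed``.  A short hash of the config is
embedded in the run manifest so outputs are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

ALLOWED_SCALES = {1, 3, 6, 12}


class PeriodSpec(BaseModel):
    start: int
    end: int

    @model_validator(mode="after")
    def _ordered(self):
        if self.end < self.start:
            raise ValueError(f"period end {self.end} before start {self.start}")
        return self


class ScenarioSpec(BaseModel):
    name: str
    trend: float  # degC per decade; positive warms and dries


class RunConfig(BaseModel):
    seed: int = 1
    n_lon: int = Field(12, ge=2)
    n_lat: int = Field(12, ge=2)
    start_year: int = 2000
    train_period: PeriodSpec = PeriodSpec(start=2000, end=2019)
    test_period: PeriodSpec = PeriodSpec(start=2020, end=2021)
    future_start: int = 2022
    future_years: int = Field(30, ge=30)
    future_periods: dict[str, PeriodSpec] = {
        "near": PeriodSpec(start=2022, end=2040),
        "medium": PeriodSpec(start=2041, end=2051),
    }
    scales: list[int] = [1, 3, 6, 12]
    thresholds: list[float] = [-0.5, -1.0]
    model_scale: int = 3
    model_threshold: float = -0.5
    min_duration: int = Field(3, ge=1)
    response: Literal["binomial", "binary"] = "binomial"
    bandwidth: int | Literal["auto", "global"] = "auto"
    calibration: Literal["self", "historical"] = "self"
    scenarios: list[ScenarioSpec] = [
        ScenarioSpec(name="SSP126", trend=-0.3),
        ScenarioSpec(name="SSP245", trend=0.5),
        ScenarioSpec(name="SSP370", trend=1.0),
        ScenarioSpec(name="SSP585", trend=1.5),
    ]
    n_ensemble_members: int = Field(3, ge=1)
    forest_mask_threshold: float = Field(0.5, ge=0.0, le=1.0)
    drought_amplitude: float = 3.0
    out_dir: str = "runs/demo"

    @field_validator("scales")
    @classmethod
    def _scales_allowed(cls, v):
        bad = set(v) - ALLOWED_SCALES
        if bad:
            raise ValueError(f"scales {sorted(bad)} outside {sorted(ALLOWED_SCALES)}")
        if not v:
            raise ValueError("at least one scale required")
        return v

    @field_validator("thresholds")
    @classmethod
    def _thresholds_negative(cls, v):
        if any(t >= 0 for t in v):
            raise ValueError("drought thresholds must be negative")
        return v

    @field_validator("bandwidth")
    @classmethod
    def _bandwidth_positive(cls, v):
        if isinstance(v, int) and v < 3:
            raise ValueError("explicit bandwidth must be >= 3 neighbours")
        return v

    @model_validator(mode="after")
    def _periods_disjoint(self):
        spans = [(self.train_period.start, self.train_period.end),
                 (self.test_period.start, self.test_period.end)]
        spans += [(p.start, p.end) for p in self.future_periods.values()]
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError(f"overlapping periods: [{s0},{e0}] and starting {s1}")
        if self.model_scale not in self.scales:
            raise ValueError("model_scale must be among scales")
        if self.model_threshold not in self.thresholds:
            raise ValueError("model_threshold must be among thresholds")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
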