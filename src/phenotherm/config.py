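"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class FittingConfig(BaseModel):
    """Stage fitting windows (°C) and nonlinear candidate families."""

    model_config = ConfigDict(extra="forbid")

    # sub-optimal windows for the linear degree-day fit; the supra-optimal
    # 37 °C point is excluded by default
    linear_windows: dict[str, tuple[float, float]] = Field(
        default={"egg": (15.0, 35.0), "nymph": (20.0, 35.0),
                 "pre_adult": (20.0, 35.0)})
    development_candidates: dict[str, list[str]] = Field(
        default={"egg": ["logan1"], "nymph": ["allahyari"],
                 "pre_adult": ["allahyari"]})
    mortality_candidates: dict[str, list[str]] = Field(
        default={"egg": ["wang2"], "nymph": ["wang2"],
                 "pre_adult": ["wang3"]})
    n_starts: int = 25
    fit_seed: int = 0


class SimulationConfig(BaseModel):
    """Cohort-simulation settings (the six-temperature replicated design)."""

    model_config = ConfigDict(extra="forbid")

    temperatures: list[float] = Field(
        default=[20.0, 23.0, 25.0, 30.0, 35.0, 37.0])
    n_eggs: int = 100
    n_reps: int = 6
    seed: int = 0
    horizon: int = 1500


class MappingConfig(BaseModel):
    """Optional climate-grid mapping settings."""

    model_config = ConfigDict(extra="forbid")

    grid_dir: str
    delta_t: list[float] = Field(default=[0.0])


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    observations: str
    out_dir: str
    female_ratio: float = 0.5
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    mapping: Optional[MappingConfig] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.model_validate(data)
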