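"""Pipeline configuration: a single validated structure holding acquisition
settings, reliability-check thresholds, relaxivity, dose, AIF options and
solver controls.  Loaded from YAML; unknown keys are rejected."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errormap import CheckThresholds
from .signal import AcquisitionParams
from .tofts import PKParams, SolverControls


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Strict):
    tr: float = 4.0                 # ms
    te: float = 1.7                 # ms
    flip_angle: float = 18.0        # degrees
    frame_interval: float = 3.0     # s
    n_frames: int = 181

    def to_params(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class ThresholdsConfig(_Strict):
    gd_sd_max: float = 5.0          # mM
    gd_mean_min: float = 0.01       # mM
    ktrans_max: float = 10.0        # min^-1
    kep_max: float = 15.0           # min^-1
    ve_limit: float = 1.0           # fail on ve >= limit (boundary fails)
    vp_limit: float = 1.0
    rel_tol: float = 1e-6
    max_iter: int = 100
    post_pre_var_ratio_max: Optional[float] = None  # optional alternative test

    def to_thresholds(self) -> CheckThresholds:
        return CheckThresholds(**self.model_dump())


class ModelAifConfig(_Strict):
    """Population AIF parameters (literature-derived defaults)."""

    a1: float = 3.99                # kg/l
    a2: float = 4.78                # kg/l
    m1: float = 0.144               # min^-1
    m2: float = 0.0111              # min^-1
    junction_time: float = 45.0     # s past bolus arrival

    def to_params(self):
        from .aif import ModelAifParams

        return ModelAifParams(**self.model_dump())


class AifConfig(_Strict):
    form: Literal["model", "individual", "average"] = "model"
    onset: float = 30.0             # bolus arrival, s from series start
    t10_blood: Optional[float] = None  # ms; None -> median T1 in artery mask
    arrival_frac: float = 0.1       # peak fraction defining bolus arrival
    model: ModelAifConfig = Field(default_factory=ModelAifConfig)


class SolverConfig(_Strict):
    rel_tol: float = 1e-6
    max_iter: int = 100
    init_ktrans: float = 0.1        # min^-1
    init_ve: float = 0.2
    init_vp: float = 0.01

    def to_controls(self) -> SolverControls:
        return SolverControls(rel_tol=self.rel_tol, max_iter=self.max_iter)

    def to_init(self) -> PKParams:
        return PKParams(ktrans=self.init_ktrans, ve=self.init_ve, vp=self.init_vp)


class PipelineConfig(_Strict):
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    thresholds: ThresholdsConfig = Field(default_factory=ThresholdsConfig)
    aif: AifConfig = Field(default_factory=AifConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    r1: float = 3.6                 # relaxivity, l mmol^-1 s^-1
    dose: float = 0.1               # mmol/kg
    hematocrit: float = 0.42
    baseline_frames: int = 10
    t1_max: float = 10_000.0        # ms, T1-fit validity ceiling
    seed: int = 0
    palette: Optional[dict[str, tuple[int, int, int]]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        return self


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
    return path
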