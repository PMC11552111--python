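"""Pipeline configuration: a strict, YAML-serialisable schema.

Unknown keys are rejected (``extra="forbid"``) so a typo in a config file
fails loudly instead of silently running defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import CovariatePrevalences, HazardConfig
from .errors import ConfigurationError
from .phantom import PhantomGeometry, ReferenceCalibration
from .scoring import ScoringTolerances

__all__ = ["PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Strict):
    mean: dict[str, float] = Field(default_factory=lambda: {
        "gm": 9.45, "liver": 2.96, "wm": 2.81, "mediastinum": 1.80, "csf": 1.50})
    sd: dict[str, float] = Field(default_factory=lambda: {
        "gm": 2.01, "liver": 0.42, "wm": 0.58, "mediastinum": 0.36, "csf": 0.34})

    def build(self) -> ReferenceCalibration:
        cal = ReferenceCalibration(mean=dict(self.mean), sd=dict(self.sd))
        cal.validate()
        return cal


class GeometryConfig(_Strict):
    preset: str = "default"  # "default" (2 mm / 128^3) | "coarse" (3 mm / 64^3)
    psf_fwhm: float = 5.0
    noise_cv: float = 0.05

    def build(self) -> PhantomGeometry:
        if self.preset == "default":
            geo = PhantomGeometry()
        elif self.preset == "coarse":
            geo = PhantomGeometry.coarse()
        else:
            raise ConfigurationError(f"unknown geometry preset {self.preset!r}")
        geo.psf_fwhm = self.psf_fwhm
        geo.noise_cv = self.noise_cv
        geo.validate()
        return geo


class HazardModel(_Strict):
    baseline_hazard: float = HazardConfig.baseline_hazard
    log_hr_ims45: float = HazardConfig.log_hr_ims45
    log_hr_ims5_extra: float = HazardConfig.log_hr_ims5_extra
    censor_rate: float = HazardConfig.censor_rate
    admin_horizon: float = HazardConfig.admin_horizon
    post_progression_rate: float = HazardConfig.post_progression_rate

    def build(self) -> HazardConfig:
        hz = HazardConfig(**self.model_dump())
        hz.validate()
        return hz


class PipelineConfig(_Strict):
    """Everything one run needs; one master seed covers all stages."""

    mode: str = "PET_CT"  # "PET_CT" | "PET_MR"
    n_patients: int = 38
    seed: int = 0
    score_distribution: list[float] | None = None  # defaults per mode
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    hazard: HazardModel = Field(default_factory=HazardModel)
    ims3_band: float = 0.10
    reader_agreement: float = 0.95
    dose_mci: float = 7.0
    weight_g: float = 70000.0
    simulate_volumes: bool = True
    out_dir: str = "results"

    @field_validator("mode")
    @classmethod
    def _mode_ok(cls, v: str) -> str:
        if v not in ("PET_CT", "PET_MR"):
            raise ValueError(f"mode must be PET_CT or PET_MR, got {v!r}")
        return v

    @field_validator("n_patients")
    @classmethod
    def _n_ok(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"n_patients must be >= 1, got {v}")
        return v

    def tolerances(self) -> ScoringTolerances:
        tol = ScoringTolerances(ims3_band=self.ims3_band)
        tol.validate()
        return tol

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(data)
        except Exception as exc:
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path
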