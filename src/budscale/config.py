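"""Run configuration: validated defaults for every pipeline stage.

Configurations are YAML (or JSON) mappings; every block is optional and
missing values fall back to the documented defaults — the water-at-30-degC
medium constants, the 0.72-1.65 mW.m^2/s optimal band and the nominal
vessel presets.  Unknown keys are rejected outright: with a predictor that
scales as d**11, a silently ignored typo in a constant is the worst
possible failure mode.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .colocalization import OverlapAnalyzer
from .hydrodynamics import MediumProperties, RegimeBand, VesselGeometry
from .size_quant import MaterialSegmenter

__all__ = ["RunConfig", "load_config", "save_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MediumBlock(_Block):
    rho: float = Field(995.67, gt=0, description="liquid density, kg/m^3")
    eta_app: float = Field(7.97e-4, gt=0, description="apparent dynamic viscosity, Pa.s")
    nu: float = Field(8.005e-7, gt=0, description="kinematic viscosity, m^2/s")
    diffusion_coeff: float = Field(2.5655e-5, gt=0, description="O2 diffusion coefficient, m^2/s")
    gravity: float = Field(9.807, gt=0, description="gravitational acceleration, m/s^2")


class BandBlock(_Block):
    lower: float = Field(0.72, gt=0)
    upper: float = Field(1.65, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lower < self.upper:
            raise ValueError(f"regime band inverted: lower={self.lower} >= upper={self.upper}")
        return self


class VesselBlock(_Block):
    inner_diameter_m: float = Field(gt=0)
    orbit_diameter_m: float = Field(0.05, gt=0)
    label: str = ""


def _check_threshold(v):
    if isinstance(v, str) and v not in ("isodata", "otsu"):
        raise ValueError(f"unknown threshold method {v!r}")
    return v


class SegmentationBlock(_Block):
    sigma: float = Field(0.0, ge=0)
    threshold: Union[str, float] = "isodata"
    min_object_px: int = Field(1, ge=1)
    min_bundle_area_px: int = Field(100, ge=1)

    _thr = field_validator("threshold")(_check_threshold)


class ColocBlock(_Block):
    cell_threshold: Union[str, float] = "otsu"
    stain_threshold: Union[str, float] = "otsu"
    closing_radius: int = Field(5, ge=0)
    denominator: str = "cellfree"

    _thr = field_validator("cell_threshold", "stain_threshold")(_check_threshold)

    @field_validator("denominator")
    @classmethod
    def _known_denominator(cls, v):
        if v not in ("cellfree", "roi"):
            raise ValueError(f"unknown denominator {v!r}")
        return v


class FitBlock(_Block):
    band_fraction: float = Field(0.5, gt=0, lt=1)
    aggregate_replicates: bool = True


_DEFAULT_PRESETS = {
    "125mL": VesselBlock(inner_diameter_m=0.066, label="125 mL Erlenmeyer (assumed d)"),
    "250mL": VesselBlock(inner_diameter_m=0.085, label="250 mL Erlenmeyer (assumed d)"),
    "500mL": VesselBlock(inner_diameter_m=0.105, label="500 mL Erlenmeyer (assumed d)"),
}


class RunConfig(_Block):
    """Validated configuration for a complete pipeline run."""

    medium: MediumBlock = MediumBlock()
    regime_band: BandBlock = BandBlock()
    vessel_presets: dict[str, VesselBlock] = Field(default_factory=lambda: dict(_DEFAULT_PRESETS))
    segmentation: SegmentationBlock = SegmentationBlock()
    coloc: ColocBlock = ColocBlock()
    fit: FitBlock = FitBlock()
    log_level: str = "INFO"
    seed: int = 0

    # --- converters to the domain objects the library consumes ---

    def medium_properties(self) -> MediumProperties:
        return MediumProperties(**self.medium.model_dump())

    def band(self) -> RegimeBand:
        return RegimeBand(self.regime_band.lower, self.regime_band.upper)

    def vessel(self, preset: str) -> VesselGeometry:
        block = self.vessel_presets[preset]
        return VesselGeometry(block.inner_diameter_m, block.orbit_diameter_m, block.label)

    def segmenter(self) -> MaterialSegmenter:
        return MaterialSegmenter(**self.segmentation.model_dump())

    def overlap_analyzer(self) -> OverlapAnalyzer:
        return OverlapAnalyzer(**self.coloc.model_dump())

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    ``None`` or an empty file yields the full default configuration.
    Malformed files, negative constants, inverted bands and unknown keys
    all raise ``ValueError`` with a descriptive message.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed configuration file {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration {path}: {exc}") from exc


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write a configuration back to YAML; load_config inverts this exactly."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
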