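"""Validated configuration models for the synthetic generator and the analysis.

All length scales are micrometres unless the field name says ``_px``.
Defaults encode the study conditions the package is calibrated for:
a 1,000x confocal field digitised at 0.5 um/px, vessel inner calibers
drawn per class from log-normal laws whose pooled quartiles sit in the
3-8 um regime, an endosteal window of 40 um, a perivascular window of
20 um and a bone-contact window of 10 um.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

VESSEL_CLASSES = ("A", "EA", "cEA", "NCLT", "NC")
#: classes with a tubular 3-D shape; NC are single cells / small clusters
TUBULAR_CLASSES = ("A", "EA", "cEA", "NCLT")

VesselClass = Literal["A", "EA", "cEA", "NCLT", "NC"]


class ClassICParams(BaseModel):
    """Log-normal law for one class's inner caliber (IC), on the log-um scale.

    ``truncate_um`` right-truncates the law (rejection sampling), used for
    capillary-like tubes whose calibers never reach the arteriolar range.
    ``zero_lumen_fraction`` is the probability that a structure of this class
    shows no measurable lumen at all (IC recorded as 0).
    """

    model_config = ConfigDict(extra="forbid")

    mu: float
    sigma: float = Field(gt=0)
    truncate_um: Optional[float] = Field(default=None, gt=0)
    zero_lumen_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    compression: Optional[float] = Field(default=None, gt=0, le=1)


class NoiseParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    poisson_scale: float = Field(default=1.0, gt=0)
    gaussian_sd: float = Field(default=2.0, ge=0)
    background_level: float = Field(default=0.5, ge=0)


class ImhcPlacement(BaseModel):
    """Placement law for immature hematopoietic cell (imHC) centroids.

    ``clustered_fraction`` of the points get a distance-to-nearest-target
    drawn from Exponential(``shell_decay_um``); the remainder are uniform
    over the marrow area (bone and vessel lumens excluded).
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["uniform", "shell"] = "uniform"
    shell_center: Literal["A", "EA", "cEA", "NCLT", "NC", "bone"] = "NCLT"
    shell_decay_um: float = Field(default=8.0, gt=0)
    clustered_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    n_points: int = Field(default=50, ge=0)

    @model_validator(mode="after")
    def _shell_implies_fraction(self) -> "ImhcPlacement":
        if self.mode == "uniform" and self.clustered_fraction > 0:
            raise ValueError("uniform mode requires clustered_fraction == 0")
        return self


def _default_ic_params() -> dict:
    # Calibrated so the pooled non-zero IC quartiles at the published class
    # counts land near the 3.2 / 4.5 / 7.6 um cut-offs.
    return {
        "A": ClassICParams(mu=math.log(11.0), sigma=0.20),
        "EA": ClassICParams(mu=math.log(5.9), sigma=0.14),
        "cEA": ClassICParams(mu=math.log(4.1), sigma=0.13, compression=0.65),
        "NCLT": ClassICParams(
            mu=math.log(3.0), sigma=0.35, truncate_um=4.1, zero_lumen_fraction=0.70
        ),
        "NC": ClassICParams(mu=0.0, sigma=1.0, zero_lumen_fraction=1.0),
    }


def _default_counts() -> dict:
    return {"NCLT": 268, "EA": 58, "cEA": 39, "A": 58, "NC": 64}


def _default_pericytes() -> dict:
    return {"A": True, "EA": True, "cEA": True, "NCLT": False, "NC": False}


def _default_bone_presence() -> dict:
    # per-class probability that a field of view includes a bone trabecula
    return {"NCLT": 0.457, "EA": 0.316, "cEA": 0.316, "A": 0.241, "NC": 0.437}


class FixtureConfig(BaseModel):
    """Full description of a synthetic micrograph dataset."""

    model_config = ConfigDict(extra="forbid")

    image_size_px: Tuple[int, int] = (512, 512)
    um_per_px: float = Field(default=0.5, gt=0)
    n_vessels_per_class: dict = Field(default_factory=_default_counts)
    ic_lognormal_params: dict = Field(default_factory=_default_ic_params)
    has_pericytes: dict = Field(default_factory=_default_pericytes)
    pericyte_ring_um: float = Field(default=1.5, gt=0)
    wall_thickness_um: float = Field(default=2.0, gt=0)
    membrane_um: float = Field(default=2.0, gt=0)
    marker_offset_px: int = Field(default=1, ge=0)
    vessels_per_image: int = Field(default=10, ge=1)
    bone_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    bone_presence: dict = Field(default_factory=_default_bone_presence)
    imhc_placement: ImhcPlacement = Field(default_factory=ImhcPlacement)
    noise: NoiseParams = Field(default_factory=NoiseParams)
    crosstalk: float = Field(default=0.0, ge=0.0, lt=1.0)
    signal_level: float = Field(default=2000.0, gt=0)
    psf_sigma_um: float = Field(default=0.5, ge=0)
    autofluorescence_level: float = Field(default=0.10, ge=0.0, lt=1.0)
    control_offset_px: Tuple[int, int] = (100, 100)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FixtureConfig":
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px entries must be positive")
        for cls, n in self.n_vessels_per_class.items():
            if cls not in VESSEL_CLASSES:
                raise ValueError(f"unknown vessel class {cls!r}")
            if int(n) < 0:
                raise ValueError(f"negative count for class {cls!r}")
        for cls in self.n_vessels_per_class:
            if cls not in self.ic_lognormal_params:
                raise ValueError(f"missing IC parameters for class {cls!r}")
        self.ic_lognormal_params = {
            k: v if isinstance(v, ClassICParams) else ClassICParams(**v)
            for k, v in self.ic_lognormal_params.items()
        }
        return self


class AnalysisConfig(BaseModel):
    """Spatial-analysis windows and reporting conventions."""

    model_config = ConfigDict(extra="forbid")

    endosteal_window_um: float = Field(default=40.0, gt=0)
    perivascular_window_um: float = Field(default=20.0, gt=0)
    bone_contact_window_um: float = Field(default=10.0, gt=0)
    qq_plotting_positions: Literal["midpoint", "blom"] = "midpoint"
    z_rounding: Literal["nearest"] = "nearest"
    sw_alpha: float = Field(default=0.05, gt=0, lt=1)
    z_skew_threshold: float = Field(default=2.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "AnalysisConfig":
        if not (
            0
            < self.bone_contact_window_um
            < self.perivascular_window_um
            < self.endosteal_window_um
        ):
            raise ValueError(
                "windows must satisfy 0 < bone_contact_window_um"
                " < perivascular_window_um < endosteal_window_um"
            )
        return self


class ColocConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    offsets_px: Tuple[int, int] = (100, 100)
    above_threshold_rule: Literal["either", "both"] = "either"
    uncorrelated_band: float = Field(default=0.02, ge=0, lt=1)
    m1_channel: Literal["red_in_green", "green_in_red"] = "red_in_green"
    dunn_adjust: Literal["bonferroni"] = "bonferroni"


class RunConfig(BaseModel):
    """Top-level pipeline configuration (one input mode, one seed)."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["synthetic", "tables"] = "synthetic"
    stages: Tuple[str, ...] = ("fixtures", "coloc", "morphometry", "spatial")
    fixture: FixtureConfig = Field(default_factory=FixtureConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    coloc: ColocConfig = Field(default_factory=ColocConfig)
    distance_table: Optional[str] = None
    vessel_table: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _stages_known(self) -> "RunConfig":
        known = {"fixtures", "coloc", "morphometry", "spatial"}
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if self.mode == "tables" and not (self.distance_table or self.vessel_table):
            raise ValueError("tables mode needs distance_table and/or vessel_table")
        return self
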