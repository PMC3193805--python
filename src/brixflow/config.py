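"""Validated pipeline configuration with YAML round-tripping.

Every tunable of the simulate / fit / growth / stats stages lives here so a
run is fully described by one file plus a seed.  Unknown keys are rejected
and schema violations are reported with their field paths (pydantic).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohort

__all__ = ["PipelineConfig", "load_config", "save_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GroupConfig(_Model):
    name: str
    n_tumors: int = Field(9, ge=1)
    a_effect: float = Field(1.0, gt=0)
    kel_effect: float = Field(1.0, gt=0)
    growth_modifier: float = Field(1.0, ge=0)


class AcquisitionConfig(_Model):
    n_baseline_frames: int = Field(5, ge=1)
    frame_interval_s: float = Field(12.0, gt=0)
    post_contrast_duration_min: float = Field(20.0, gt=0)
    injection_duration_s: float = Field(3.0, gt=0)


class HypoxiaConfig(_Model):
    intercept: float = Field(0.17, ge=0, le=1)
    slope: float = Field(-0.21, le=0)
    noise_sd: float = Field(0.02, ge=0)


class FieldConfig(_Model):
    mean: float = Field(gt=0)
    voxel_cv: float = Field(0.15, ge=0)
    tumor_cv: float = Field(0.12, ge=0)


def _default_group_configs() -> list[GroupConfig]:
    return [
        GroupConfig(
            name=g.name,
            n_tumors=g.n_tumors,
            a_effect=g.a_effect,
            kel_effect=g.kel_effect,
            growth_modifier=g.growth_modifier,
        )
        for g in cohort.default_groups()
    ]


class SimulationConfig(_Model):
    groups: list[GroupConfig] = Field(default_factory=_default_group_configs)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    noise_sd: float = Field(0.05, ge=0)
    hypoxia_coupling: HypoxiaConfig = Field(default_factory=HypoxiaConfig)
    grid_size: int = Field(32, ge=4)
    roi_semi_axes: tuple[float, float] = (12.6, 10.1)
    parameter_fields: dict[str, FieldConfig] = Field(
        default_factory=lambda: {
            "A": FieldConfig(mean=1.2, voxel_cv=0.15, tumor_cv=0.12),
            "k_ep": FieldConfig(mean=3.0, voxel_cv=0.20, tumor_cv=0.15),
            "k_el": FieldConfig(mean=0.25, voxel_cv=0.15, tumor_cv=0.12),
        }
    )
    smoothing_sigma: float = Field(2.0, ge=0)
    baseline_signal: float = Field(1000.0, gt=0)
    growth_base_rate: float = Field(0.132, ge=0)
    growth_saturation_day: float = Field(30.0, gt=0)
    growth_rate_cv: float = Field(0.10, ge=0)
    caliper_noise_sd_mm: float = Field(0.2, ge=0)
    measurement_days: tuple[int, ...] = tuple(range(0, 29, 4))
    # per-tumor actual injection durations drawn uniformly from this range;
    # null disables the jitter (actual == nominal)
    injection_jitter_s: Optional[tuple[float, float]] = (2.0, 6.0)

    @model_validator(mode="after")
    def _check_fields(self):
        missing = {"A", "k_ep", "k_el"} - set(self.parameter_fields)
        if missing:
            raise ValueError(f"parameter_fields missing: {sorted(missing)}")
        if self.injection_jitter_s is not None:
            lo, hi = self.injection_jitter_s
            if not 0 < lo <= hi:
                raise ValueError("injection_jitter_s must satisfy 0 < lo <= hi")
        return self

    def to_design(self, seed: int) -> cohort.CohortDesign:
        return cohort.CohortDesign(
            groups=tuple(
                cohort.GroupSpec(
                    name=g.name,
                    n_tumors=g.n_tumors,
                    a_effect=g.a_effect,
                    kel_effect=g.kel_effect,
                    growth_modifier=g.growth_modifier,
                )
                for g in self.groups
            ),
            acquisition=cohort.AcquisitionProtocol(
                n_baseline_frames=self.acquisition.n_baseline_frames,
                frame_interval_s=self.acquisition.frame_interval_s,
                post_contrast_duration_min=self.acquisition.post_contrast_duration_min,
                injection_duration_s=self.acquisition.injection_duration_s,
            ),
            noise_sd=self.noise_sd,
            hypoxia_coupling=cohort.HypoxiaCoupling(
                intercept=self.hypoxia_coupling.intercept,
                slope=self.hypoxia_coupling.slope,
                noise_sd=self.hypoxia_coupling.noise_sd,
            ),
            seed=seed,
            grid_size=self.grid_size,
            roi_semi_axes=self.roi_semi_axes,
            parameter_fields={
                k: cohort.ParameterField(v.mean, v.voxel_cv, v.tumor_cv)
                for k, v in self.parameter_fields.items()
            },
            smoothing_sigma=self.smoothing_sigma,
            baseline_signal=self.baseline_signal,
            growth_base_rate=self.growth_base_rate,
            growth_saturation_day=self.growth_saturation_day,
            growth_rate_cv=self.growth_rate_cv,
            caliper_noise_sd_mm=self.caliper_noise_sd_mm,
            measurement_days=self.measurement_days,
        )


class FittingConfig(_Model):
    a_bounds: tuple[float, float] = (0.0, 50.0)
    kep_bounds: tuple[float, float] = (0.0, 30.0)
    kel_bounds: tuple[float, float] = (0.0, 5.0)
    tol: float = Field(1e-8, gt=0)
    max_nfev: int = Field(500, ge=1)
    r2_min: float = Field(0.5, ge=0, le=1)
    kep_qc_threshold: float = Field(0.25, ge=0, le=1)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return (self.a_bounds, self.kep_bounds, self.kel_bounds)


class GrowthConfig(_Model):
    threshold_fold: float = Field(3.0, gt=1)
    volume_convention: Literal["length_squared", "width_squared"] = "length_squared"
    control_group: str = "Control"


class StatsConfig(_Model):
    paired_within_group: bool = True
    holm_correction: bool = False


class PipelineConfig(_Model):
    seed: int = Field(0, ge=0)
    output_dir: Optional[str] = None
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)


def load_config(path: Optional[Path] = None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; an empty file gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(raw or {})


def save_config(config: PipelineConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
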