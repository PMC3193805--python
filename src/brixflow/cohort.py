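"""Seeded virtual xenograft cohorts for exercising the analysis pipeline.

The generator emulates the structure of a five-arm prostate-xenograft
radiochemotherapy experiment: per-voxel contrast-enhancement curves from the
Brix model on an elliptical single-slice ROI, pre- to post-treatment
multiplicative shifts of the amplitude A and elimination rate k_el per
treatment arm, caliper growth trajectories with arm-dependent inhibition,
and per-tumor hypoxic fractions negatively coupled to the A-parameter
change.  Every draw is a pure function of (design, indices, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .growth import TumorGrowthRecord
from .kinetics import DCESeries
from .model import brix_rsi

__all__ = [
    "GroupSpec",
    "AcquisitionProtocol",
    "HypoxiaCoupling",
    "ParameterField",
    "CohortDesign",
    "GroundTruth",
    "default_groups",
    "default_design",
    "generate_parameter_maps",
    "simulate_dce",
    "simulate_growth",
    "simulate_hypoxic_fraction",
]

Session = Literal["pre", "post"]

# internal stage codes for seed derivation
_STAGE_MAPS = 1
_STAGE_DCE = 2
_STAGE_GROWTH = 3
_STAGE_HYPOXIA = 4


@dataclass(frozen=True)
class GroupSpec:
    """One treatment arm: effect multipliers act pre -> post."""

    name: str
    n_tumors: int = 9
    a_effect: float = 1.0
    kel_effect: float = 1.0
    growth_modifier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if self.a_effect <= 0 or self.kel_effect <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.growth_modifier < 0:
            raise ValueError("growth_modifier must be >= 0")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Dynamic acquisition grid: baseline block, then post-contrast frames."""

    n_baseline_frames: int = 5
    frame_interval_s: float = 12.0
    post_contrast_duration_min: float = 20.0
    injection_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.post_contrast_duration_min <= 0:
            raise ValueError("post_contrast_duration_min must be positive")
        if self.injection_duration_s <= 0:
            raise ValueError("injection_duration_s must be positive")

    def frame_times_min(self) -> tuple[np.ndarray, int]:
        """(frame times in minutes relative to injection, n_baseline)."""
        dt = self.frame_interval_s / 60.0
        nb = self.n_baseline_frames
        n_post = int(round(self.post_contrast_duration_min / dt))
        baseline = dt * (np.arange(nb) - (nb - 1))
        post = dt * np.arange(1, n_post + 1)
        return np.concatenate([baseline, post]), nb


@dataclass(frozen=True)
class HypoxiaCoupling:
    """Linear coupling of hypoxic fraction to relative A-change (fractions)."""

    intercept: float = 0.17
    slope: float = -0.21
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.slope > 0:
            raise ValueError("hypoxia coupling slope must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ParameterField:
    """Log-normal spatial field spec: tissue mean, voxel CV, tumor-level CV."""

    mean: float
    voxel_cv: float
    tumor_cv: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("field mean must be positive")
        if self.voxel_cv < 0 or self.tumor_cv < 0:
            raise ValueError("CVs must be >= 0")


def default_groups() -> tuple[GroupSpec, ...]:
    """The five-arm design with the default effect structure.

    A-effects mirror group-mean relative A changes of (-18, -26, +4, +20,
    +29) % and k_el-effects (+45, +85, +47, -27, -27) %; growth modifiers
    are graded so the untreated arm grows fastest and radiotherapy alone
    slows growth the most.
    """
    return (
        GroupSpec("Control", 9, 0.82, 1.45, 1.00),
        GroupSpec("PL-DXR", 9, 0.74, 1.85, 0.75),
        GroupSpec("PL-DXR + hypoxic RT", 9, 1.04, 1.47, 0.40),
        GroupSpec("Hypoxic RT", 9, 1.20, 0.73, 0.55),
        GroupSpec("RT", 9, 1.29, 0.73, 0.25),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a virtual cohort; every draw derives from `seed`."""

    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    acquisition: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    noise_sd: float = 0.05  # fraction of baseline signal
    hypoxia_coupling: HypoxiaCoupling = field(default_factory=HypoxiaCoupling)
    seed: int = 0
    grid_size: int = 32
    roi_semi_axes: tuple[float, float] = (12.6, 10.1)
    parameter_fields: dict = field(
        default_factory=lambda: {
            "A": ParameterField(1.2, 0.15, 0.12),
            "k_ep": ParameterField(3.0, 0.20, 0.15),
            "k_el": ParameterField(0.25, 0.15, 0.12),
        }
    )
    smoothing_sigma: float = 2.0
    baseline_signal: float = 1000.0
    # growth generator knobs
    growth_base_rate: float = 0.132  # per day; untreated arm crosses 3-fold near day 10
    growth_saturation_day: float = 30.0
    growth_rate_cv: float = 0.10
    caliper_noise_sd_mm: float = 0.2
    measurement_days: tuple[int, ...] = tuple(range(0, 29, 4))

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("need at least one group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_size < 4:
            raise ValueError("grid too small")
        for key in ("A", "k_ep", "k_el"):
            if key not in self.parameter_fields:
                raise ValueError(f"missing parameter field spec: {key}")

    def group_index(self, name: str) -> int:
        for i, g in enumerate(self.groups):
            if g.name == name:
                return i
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Per-tumor, per-session ground-truth parameter maps over the ROI."""

    A: np.ndarray
    k_ep: np.ndarray
    k_el: np.ndarray
    roi_mask: np.ndarray
    group: str
    tumor_index: int
    session: Session
    hypoxic_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        inside = self.roi_mask
        if inside.sum() == 0:
            raise ValueError("ROI mask is empty")
        for name in ("A", "k_ep", "k_el"):
            vals = getattr(self, name)[inside]
            if np.any(vals <= 0):
                raise ValueError(f"{name} must be positive inside the ROI")
        if self.hypoxic_fraction is not None and not 0 <= self.hypoxic_fraction <= 1:
            raise ValueError("hypoxic fraction must be in [0, 1]")


def _rng(design_seed: int, stage: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(design_seed, spawn_key=(stage, *key))
    )


def _elliptical_mask(grid_size: int, semi_axes: tuple[float, float]) -> np.ndarray:
    c = (grid_size - 1) / 2.0
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    a, b = semi_axes
    return ((cols - c) / a) ** 2 + ((rows - c) / b) ** 2 <= 1.0


def _lognormal_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean: float,
    cv: float,
    smooth_sigma: float,
) -> np.ndarray:
    if cv == 0:
        return np.full(shape, mean)
    z = rng.standard_normal(shape)
    if smooth_sigma > 0:
        z = gaussian_filter(z, smooth_sigma, mode="reflect")
        z = (z - z.mean()) / z.std()
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(sigma * z - sigma**2 / 2.0)


def generate_parameter_maps(
    design: CohortDesign,
    group: GroupSpec | str | int,
    tumor_index: int,
    session: Session,
) -> GroundTruth:
    """Ground-truth (A, k_ep, k_el) maps for one tumor at one session.

    The pre-treatment maps are spatially smooth log-normal fields on an
    elliptical single-slice ROI; the post-treatment maps are the same fields
    scaled voxel-wise by the arm's effect multipliers, so the in-ROI mean
    post/pre ratio equals the configured multiplier exactly.
    """
    if session not in ("pre", "post"):
        raise ValueError("session must be 'pre' or 'post'")
    if isinstance(group, int):
        gi, spec = group, design.groups[group]
    elif isinstance(group, str):
        gi = design.group_index(group)
        spec = design.groups[gi]
    else:
        spec = group
        gi = design.group_index(spec.name)

    mask = _elliptical_mask(design.grid_size, design.roi_semi_axes)
    if mask.sum() == 0:
        raise ValueError("ROI mask is empty")

    rng = _rng(design.seed, _STAGE_MAPS, gi, tumor_index)
    maps = {}
    for name in ("A", "k_ep", "k_el"):
        fs: ParameterField = design.parameter_fields[name]
        tumor_factor = 1.0
        if fs.tumor_cv > 0:
            sigma_t = np.sqrt(np.log1p(fs.tumor_cv**2))
            tumor_factor = float(np.exp(sigma_t * rng.standard_normal() - sigma_t**2 / 2))
        fld = _lognormal_field(
            rng, mask.shape, fs.mean * tumor_factor, fs.voxel_cv, design.smoothing_sigma
        )
        maps[name] = np.where(mask, fld, np.nan)

    if session == "post":
        maps["A"] = maps["A"] * spec.a_effect
        maps["k_el"] = maps["k_el"] * spec.kel_effect

    return GroundTruth(
        A=maps["A"], k_ep=maps["k_ep"], k_el=maps["k_el"],
        roi_mask=mask, group=spec.name, tumor_index=tumor_index, session=session,
    )


def simulate_dce(
    truth: GroundTruth,
    design: CohortDesign,
    seed: int,
    *,
    actual_injection_duration_s: Optional[float] = None,
) -> DCESeries:
    """Forward-simulate a dynamic series from ground-truth parameter maps.

    In-ROI post-contrast signal is baseline * (1 + RSI_Brix(t)); baseline
    frames and out-of-ROI voxels carry no enhancement.  Additive Gaussian
    noise with SD ``noise_sd * baseline`` is applied to every frame.  When
    the actual injection took longer (shorter) than nominal, the effective
    bolus midpoint shifts and the enhancement is evaluated at
    ``t + (actual - nominal)/2`` so that the downstream time-axis correction
    aligns tumors exactly.
    """
    acq = design.acquisition
    nominal = acq.injection_duration_s
    actual = nominal if actual_injection_duration_s is None else actual_injection_duration_s
    if actual <= 0:
        raise ValueError("actual injection duration must be positive")

    times, nb = acq.frame_times_min()
    model_times = times[nb:] + (actual - nominal) / 2.0 / 60.0
    base = design.baseline_signal

    signal = np.full(truth.roi_mask.shape + (len(times),), base, dtype=float)
    rows, cols = np.nonzero(truth.roi_mask)
    for r, c in zip(rows, cols):
        rsi = brix_rsi(model_times, truth.A[r, c], truth.k_ep[r, c], truth.k_el[r, c])
        signal[r, c, nb:] = base * (1.0 + rsi)

    if design.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        signal = signal + rng.normal(0.0, design.noise_sd * base, size=signal.shape)
        signal = np.clip(signal, 0.0, None)

    return DCESeries(
        signal=signal,
        frame_times=times,
        n_baseline_frames=nb,
        nominal_injection_duration=nominal,
        actual_injection_duration=actual,
        roi_mask=truth.roi_mask.copy(),
    )


def simulate_growth(design: CohortDesign, seed: int) -> list[TumorGrowthRecord]:
    """Caliper growth series for every tumor in the cohort.

    Volumes follow an exponential law with saturating rate,
    V(t) = V0 * exp(g * t * (1 - t / (2 * t_sat))), with the per-tumor rate
    g scaled by the arm's growth modifier and log-normal animal-to-animal
    variation; diameters back out of the volume through a per-tumor aspect
    ratio, with Gaussian caliper reading noise.  Per-tumor draws are keyed
    by (group, tumor) index so arms are directly comparable at a fixed seed.
    """
    days = np.asarray(design.measurement_days, dtype=float)
    t_sat = design.growth_saturation_day
    records: list[TumorGrowthRecord] = []
    for gi, spec in enumerate(design.groups):
        for ti in range(spec.n_tumors):
            rng = _rng(seed, _STAGE_GROWTH, gi, ti)
            L0 = rng.uniform(6.0, 9.0)
            rho = rng.uniform(0.65, 0.95)
            v0 = np.pi / 6.0 * rho * L0**3
            g_noise = float(np.exp(design.growth_rate_cv * rng.standard_normal()))
            g = design.growth_base_rate * spec.growth_modifier * g_noise
            v = v0 * np.exp(g * days * (1.0 - days / (2.0 * t_sat)))
            length = (6.0 * v / (np.pi * rho)) ** (1.0 / 3.0)
            width = rho * length
            if design.caliper_noise_sd_mm > 0:
                length = length + rng.normal(0, design.caliper_noise_sd_mm, size=len(days))
                width = width + rng.normal(0, design.caliper_noise_sd_mm, size=len(days))
            length = np.clip(length, 0.5, None)
            width = np.clip(width, 0.3, None)
            lo = np.minimum(length, width)
            hi = np.maximum(length, width)
            records.append(
                TumorGrowthRecord(
                    tumor_id=f"{spec.name}-{ti:02d}",
                    group=spec.name,
                    days=days,
                    length_mm=hi,
                    width_mm=lo,
                )
            )
    return records


def simulate_hypoxic_fraction(
    relative_A_change: float, design: CohortDesign, seed: int
) -> float:
    """Pimonidazole-style hypoxic fraction coupled to the A-parameter change.

    ``intercept + slope * relative_A_change`` (fractions, slope <= 0) plus
    Gaussian noise, clipped to [0, 1].
    """
    hc = design.hypoxia_coupling
    value = hc.intercept + hc.slope * relative_A_change
    if hc.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        value += rng.normal(0.0, hc.noise_sd)
    return float(np.clip(value, 0.0, 1.0))


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The study-structured default design, optionally with field overrides."""
    return replace(CohortDesign(seed=seed), **overrides)
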