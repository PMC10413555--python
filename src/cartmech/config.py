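"""Validated run configuration (YAML-backed).

Every block is strict: unknown keys are rejected before any compute.
Units are SI throughout (metres, seconds, pascals, newtons); strains are
reported in percent downstream.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "GeometryConfig", "MaterialConfig", "LoadingConfig", "SolverBlock",
    "MetricsConfig", "OutputConfig", "RunConfig", "load_config", "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    """Plug geometry, layering and fibril architecture."""

    width_m: float = 0.03
    depth_m: float = 0.03
    thickness_m: float = 0.0025
    nx: int = 6
    ny: int = 6
    nz_per_layer: int = 1
    layer_fractions: list[float] = Field(default=[0.15, 0.15, 0.35, 0.35])
    zone_superficial: float = 0.1     # arcade zone bounds on normalised depth
    zone_deep: float = 0.5
    secondary_set_size: int = 13
    primary_fraction: float = 0.75
    fluid_fraction_surface: float = 0.90
    fluid_fraction_bone: float = 0.70
    fibril_density_surface: float = 0.35
    fibril_density_bone: float = 0.15

    @field_validator("width_m", "depth_m", "thickness_m")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("plug dimensions must be positive")
        return v


class MaterialConfig(_Strict):
    """Constitutive preset with optional overrides (Pa, Pa s, m^4/(N s))."""

    preset: Literal["cartilage_frpve", "meniscus_frpe", "bone_linear"] = "cartilage_frpve"
    G_m: Optional[float] = None
    lambda_m: Optional[float] = None
    E_0: Optional[float] = None
    E_eps: Optional[float] = None
    eta: Optional[float] = None
    k_0: Optional[float] = None
    M: Optional[float] = None
    fluid_bulk: Optional[float] = None
    strain_stiffening: bool = False


class LoadingConfig(_Strict):
    """Stance-phase archetypes and the joint-to-plug load mapping."""

    n_samples: int = 20
    body_weight_N: float = 600.0
    healthy_peak1_bw: float = 2.5
    healthy_peak2_bw: float = 2.2
    koa_force_gain: float = 1.15        # KOA peak-force multiplier vs healthy
    koa_adduction_scale: float = 1.2
    koa_cop_shift_lat_mm: float = 2.9   # posterior COP shift per compartment
    koa_cop_shift_med_mm: float = 5.1
    noise_rel: float = 0.02
    medial_split: float = 0.6
    indenter_shape: Literal["sphere", "flat"] = "sphere"
    indenter_radius_m: float = 0.035    # femoral-condyle-like curvature
    indenter_half_width_m: float = 0.006
    # joint-to-plug force scale: the default keeps the plug in the 10-20%
    # compression regime of loaded knee cartilage (the desk-scale plug lacks
    # the swelling pretension and lateral continuity that stiffen tissue in
    # situ); None = preserve nominal contact pressure instead
    force_scale: Optional[float] = 0.012
    nominal_contact_area_m2: float = 450e-6
    tilt_per_Nm: float = 5e-4
    use_tilt: bool = True
    use_cop_offset: bool = True


class SolverBlock(_Strict):
    rtol: float = 1e-6
    max_iter: int = 50
    penalty_Pa_per_m: float = 1e12
    force_tol: float = 0.005
    max_halvings: int = 10
    stab_beta: float = 0.25
    step_cap: float = 0.4
    contact_reg_m: float = 1e-8
    contact_edge_band_m: float = 5e-4
    pressure_smoothing: bool = False


class MetricsConfig(_Strict):
    filter: Literal["footprint", "strain-floor", "none"] = "footprint"
    strain_floor_pct: float = 1.0
    mss_threshold_pct: float = 30.0
    sfd_threshold_pct: float = 10.0


class OutputConfig(_Strict):
    write_vtk: bool = False
    write_fields_csv: bool = True


class RunConfig(_Strict):
    """Top-level configuration of a healthy-vs-KOA comparison run."""

    seed: int = 0
    out_dir: str = "runs/out"
    stance_duration_s: float = 0.6
    tissue: Literal["cartilage", "meniscus"] = "cartilage"
    compartments: list[Literal["medial", "lateral"]] = Field(
        default=["medial", "lateral"])
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    loading: LoadingConfig = Field(default_factory=LoadingConfig)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; schema errors abort before compute."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the config."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
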