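"""Synthetic stance-phase loading: healthy and KOA-like gait archetypes.

Musculoskeletal gait pipelines deliver, per stance percentage, the
superior-inferior tibiofemoral contact force, knee flexion angle,
anterior-posterior and medial-lateral translations, internal-external
rotation and the varus-valgus (adduction) moment.  The subject recordings
behind such pipelines are typically access-restricted, so this module
*emulates* them: smooth gait-literature template curves scaled by
archetype parameters, with optional smooth low-amplitude noise from a
seeded generator.  Real exported curves can be substituted through the
CSV reader, which round-trips the full channel set losslessly.

The KOA-like archetype differs from the healthy archetype by a higher
peak contact force (+15% by default), a larger adduction-moment scale
(+20%) and a posterior shift of the per-compartment centre of pressure
(2.9 mm lateral, 5.1 mm medial by default).

Sign conventions: x anterior(+)/posterior(-); COP offsets are along x.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fe import RigidIndenter, TimeSchedule
from .mesh import Mesh

__all__ = [
    "StanceProfile",
    "SubjectArchetype",
    "MediolateralSplit",
    "generate_stance_profile",
    "map_profile_to_schedule",
    "write_profile_csv",
    "read_profile_csv",
    "healthy_archetype",
    "koa_archetype",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["stance_pct", "force_N", "flexion_deg", "ap_mm", "ml_mm",
               "ie_deg", "vv_Nm", "cop_lat_mm", "cop_med_mm"]


@dataclass
class StanceProfile:
    """Stance-phase time series on a uniform 0..100% grid."""

    stance_pct: np.ndarray     # (n,)
    force_N: np.ndarray        # superior-inferior contact force, >= 0
    flexion_deg: np.ndarray
    ap_mm: np.ndarray          # anterior-posterior translation
    ml_mm: np.ndarray          # medial-lateral translation
    ie_deg: np.ndarray         # internal-external rotation
    vv_Nm: np.ndarray          # varus-valgus (adduction) moment
    cop_lat_mm: np.ndarray     # lateral-compartment COP offset (anterior +)
    cop_med_mm: np.ndarray     # medial-compartment COP offset

    def __post_init__(self):
        for name in CSV_COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.stance_pct.size
        for name in CSV_COLUMNS:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"channel {name} has inconsistent length")
        if np.any(self.force_N < 0):
            raise ValueError("contact force must be non-negative")
        peak = self.force_N.max()
        if peak > 0 and (self.force_N[0] > 0.05 * peak or self.force_N[-1] > 0.05 * peak):
            raise ValueError("contact force at stance ends must be <= 5% of peak")

    @property
    def peak_index(self) -> int:
        """Index of the (single) global contact-force maximum."""
        return int(np.argmax(self.force_N))

    def cop_mm(self, compartment: str) -> np.ndarray:
        if compartment == "lateral":
            return self.cop_lat_mm
        if compartment == "medial":
            return self.cop_med_mm
        raise ValueError(f"unknown compartment {compartment!r}")


@dataclass
class SubjectArchetype:
    """Parameters of a synthetic gait subject.

    Peak force multiples refer to the first (loading response) and second
    (push-off) force peaks in units of body weight.  ``cop_shift_mm``
    is the posterior COP shift per compartment relative to the template
    (positive = posterior); noise is a smooth random perturbation with
    relative amplitude ``noise_rel`` regenerated deterministically from
    ``seed``.
    """

    label: str = "healthy"
    body_weight_N: float = 600.0
    peak1_bw: float = 2.5
    peak2_bw: float = 2.2
    adduction_scale: float = 1.0
    cop_shift_lat_mm: float = 0.0
    cop_shift_med_mm: float = 0.0
    noise_rel: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.peak1_bw <= 0 or self.peak2_bw <= 0:
            raise ValueError("peak force multiples must be positive")
        if self.label == "koa" and (self.cop_shift_lat_mm < 0 or self.cop_shift_med_mm < 0):
            raise ValueError("KOA archetype posterior COP shift must be >= 0")


def healthy_archetype(seed: int = 0, **overrides) -> SubjectArchetype:
    return SubjectArchetype(label="healthy", seed=seed, **overrides)


def koa_archetype(seed: int = 0, **overrides) -> SubjectArchetype:
    """KOA-like contrast: +15% peak force, +20% adduction moment, posterior
    COP shift of 2.9 mm (lateral) / 5.1 mm (medial)."""
    kw = dict(
        label="koa",
        peak1_bw=2.5 * 1.15,
        peak2_bw=2.2 * 1.15,
        adduction_scale=1.2,
        cop_shift_lat_mm=2.9,
        cop_shift_med_mm=5.1,
    )
    kw.update(overrides)
    return SubjectArchetype(seed=seed, **kw)


@dataclass
class MediolateralSplit:
    """Per-step fraction of total force on the medial vs lateral compartment."""

    medial: np.ndarray

    def __post_init__(self):
        self.medial = np.atleast_1d(np.asarray(self.medial, dtype=float))
        if np.any((self.medial < 0) | (self.medial > 1)):
            raise ValueError("split fractions must lie in [0, 1]")

    @property
    def lateral(self) -> np.ndarray:
        return 1.0 - self.medial

    def fraction(self, compartment: str) -> np.ndarray:
        return self.medial if compartment == "medial" else self.lateral

    @classmethod
    def constant(cls, medial: float = 0.6, n: int = 1) -> "MediolateralSplit":
        return cls(medial=np.full(n, medial))


def _gauss_bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - center) / width) ** 2)


def _smoothstep_taper(s: np.ndarray, ramp: float = 10.0) -> np.ndarray:
    """C1 window: 0 at the stance ends, 1 in the middle."""
    x = np.clip(s / ramp, 0.0, 1.0)
    up = x * x * (3.0 - 2.0 * x)
    x2 = np.clip((100.0 - s) / ramp, 0.0, 1.0)
    down = x2 * x2 * (3.0 - 2.0 * x2)
    return up * down


def _smooth_noise(rng: np.random.Generator, n: int, n_ctrl: int = 9) -> np.ndarray:
    """Smooth zero-mean noise: spline through a coarse random control grid."""
    from scipy.interpolate import CubicSpline
    ctrl = rng.standard_normal(n_ctrl)
    ctrl[0] = ctrl[-1] = 0.0
    xs = np.linspace(0.0, 100.0, n_ctrl)
    return CubicSpline(xs, ctrl)(np.linspace(0.0, 100.0, n))


def generate_stance_profile(archetype: SubjectArchetype, n_samples: int = 100) -> StanceProfile:
    """Synthesise one stance phase of MSK-style outputs for an archetype.

    Deterministic given (archetype, archetype.seed, n_samples).  The force
    channel is a double-peaked curve (loading response ~25% stance,
    push-off ~75%) scaled by body-weight multiples, windowed to vanish at
    the stance ends; kinematic channels are smooth gait-shaped templates.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    s = np.linspace(0.0, 100.0, n_samples)
    rng = np.random.default_rng(archetype.seed)
    bw = archetype.body_weight_N

    taper = _smoothstep_taper(s)
    force = bw * (
        archetype.peak1_bw * _gauss_bump(s, 25.0, 10.0)
        + 0.55 * min(archetype.peak1_bw, archetype.peak2_bw) * _gauss_bump(s, 50.0, 18.0)
        + archetype.peak2_bw * _gauss_bump(s, 75.0, 10.0)
    ) * taper
    if archetype.noise_rel > 0:
        force = force * (1.0 + archetype.noise_rel * _smooth_noise(rng, n_samples)) * taper
    force = np.maximum(force, 0.0)

    flexion = 5.0 + 13.0 * _gauss_bump(s, 15.0, 9.0) + 35.0 * _gauss_bump(s, 102.0, 11.0)
    ap = 2.5 * np.sin(2 * np.pi * s / 100.0)            # mm
    ml = 0.8 * np.sin(np.pi * s / 100.0)                # mm
    ie = 4.0 * np.sin(2 * np.pi * s / 100.0 + 0.5)      # deg
    vv = archetype.adduction_scale * 40.0 * (
        _gauss_bump(s, 25.0, 12.0) + 0.85 * _gauss_bump(s, 75.0, 12.0)) * taper

    cop_base = 3.0 * np.sin(2 * np.pi * s / 100.0)      # anterior-posterior sweep, mm
    cop_lat = cop_base - archetype.cop_shift_lat_mm
    cop_med = cop_base - archetype.cop_shift_med_mm
    if archetype.noise_rel > 0:
        for arr in (flexion, ap, ml, ie, vv):
            arr += archetype.noise_rel * np.std(arr) * _smooth_noise(rng, n_samples)

    return StanceProfile(
        stance_pct=s, force_N=force, flexion_deg=flexion, ap_mm=ap, ml_mm=ml,
        ie_deg=ie, vv_Nm=vv, cop_lat_mm=cop_lat, cop_med_mm=cop_med,
    )


def map_profile_to_schedule(
    profile: StanceProfile,
    compartment: str,
    split: MediolateralSplit,
    mesh: Mesh,
    indenter: RigidIndenter,
    stance_duration_s: float = 0.6,
    force_scale: float | None = None,
    nominal_contact_area_m2: float = 450e-6,
    tilt_per_Nm: float = 5e-4,
) -> TimeSchedule:
    """Map a stance profile onto a plug-solver loading schedule.

    Per step: indenter target normal force = total force x compartment
    split fraction x force_scale; the indenter's anterior-posterior
    position follows the compartment COP offset; tilt is derived from the
    varus-valgus moment through a configurable compliance (rad per N m).

    ``force_scale`` rescales the joint-level force to the plug: the
    default preserves nominal contact pressure by the ratio of the
    indenter footprint area to a nominal per-compartment contact area;
    pass 1.0 for a raw pass-through of the split force.
    """
    if "articular" not in mesh.surface_tags:
        raise ValueError("mesh needs an 'articular' surface tag")
    n = profile.stance_pct.size
    frac = split.fraction(compartment)
    if frac.size == 1:
        frac = np.full(n, frac[0])
    if frac.size != n:
        raise ValueError("profile and medio-lateral split have mismatched lengths")

    if force_scale is None:
        if indenter.shape == "flat":
            foot = 4.0 * indenter.half_widths[0] * indenter.half_widths[1]
        else:
            foot = np.pi * indenter.radius ** 2
        force_scale = foot / nominal_contact_area_m2

    times = profile.stance_pct / 100.0 * stance_duration_s
    if times[0] <= 0.0:   # schedule times must be positive; state at t=0 is the start
        times = times + times[1] * 1e-3 if times.size > 1 else times + 1e-6
    forces = profile.force_N * frac * force_scale
    offsets = np.column_stack([
        profile.cop_mm(compartment) * 1e-3,
        np.zeros(n),
    ])
    tilt = profile.vv_Nm * tilt_per_Nm
    return TimeSchedule(
        times=times,
        indenter_force=forces,
        indenter_offset=offsets,
        indenter_tilt=tilt,
    )


def write_profile_csv(profile: StanceProfile, path) -> None:
    """Write all channels at full precision (lossless round-trip)."""
    df = pd.DataFrame({c: getattr(profile, c) for c in CSV_COLUMNS})
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path) -> StanceProfile:
    """Read a profile CSV (header-keyed; column order free)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV is missing channel column(s): {', '.join(missing)}")
    return StanceProfile(**{c: df[c].to_numpy() for c in CSV_COLUMNS})
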