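"""End-to-end desk-scale analysis: archetype loading -> plug FE -> metrics.

For each subject archetype (healthy, KOA-like) and tibial compartment
(medial, lateral) the pipeline generates a stance-phase loading schedule,
runs the fibril-reinforced biphasic plug simulation under a force-driven
indenter, evaluates the mechanoregulatory strain metrics (MSS, SFD, and
MPS for meniscus-mode runs) per element centroid and stance step, and
reduces them to volume-weighted summaries, exceedance fractions and
centre-of-pressure traces.  A comparison report aligns the two subjects.

All artifacts are plain text (CSV/JSON, optional legacy VTK) with a
manifest recording seeds, the config hash and convergence statistics.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .constitutive import (FibrilParams, MaterialParams, NonFibrillarParams,
                           PorousParams, material_preset)
from .fe import (BoundaryCondition, RigidIndenter, SolverConfig,
                 SolutionHistory, TimeSchedule, solve_transient)
from .fibrils import (DepthProfile, FibrilField, assign_split_lines,
                      build_fibril_field, circumferential_fibril_field)
from .loading import (MediolateralSplit, SubjectArchetype,
                      generate_stance_profile, healthy_archetype,
                      koa_archetype, map_profile_to_schedule,
                      write_profile_csv)
from .mesh import Mesh, build_layer_mesh
from .metrics import (MetricField, contact_volume_filter, exceedance_fraction,
                      footprint_step_mask, footprint_step_weights,
                      footprint_union_mask, metric_from_F, stance_series,
                      volume_weighted_percentiles)

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "CompartmentResult", "ComparisonReport",
           "build_plug", "archetype_from_config", "run_subject",
           "compare_subjects", "write_comparison"]


# ---------------------------------------------------------------- builders


def _material_from_config(cfg: RunConfig) -> MaterialParams:
    m = cfg.material
    base = material_preset(m.preset)
    nf = NonFibrillarParams(
        G_m=m.G_m if m.G_m is not None else base.nonfibrillar.G_m,
        lambda_m=m.lambda_m if m.lambda_m is not None else base.nonfibrillar.lambda_m,
    )
    fib = FibrilParams(
        E_0=m.E_0 if m.E_0 is not None else base.fibril.E_0,
        E_eps=m.E_eps if m.E_eps is not None else base.fibril.E_eps,
        eta=m.eta if m.eta is not None else base.fibril.eta,
        viscoelastic=base.fibril.viscoelastic,
        strain_stiffening=m.strain_stiffening,
    )
    por = PorousParams(
        k_0=m.k_0 if m.k_0 is not None else base.porous.k_0,
        M=m.M if m.M is not None else base.porous.M,
    )
    fb = m.fluid_bulk if m.fluid_bulk is not None else base.fluid_bulk
    return MaterialParams(nonfibrillar=nf, fibril=fib, porous=por, fluid_bulk=fb)


def build_plug(cfg: RunConfig):
    """Mesh, Gauss-point fibril field and centroid fibril field for one plug."""
    g = cfg.geometry
    mesh = build_layer_mesh(g.width_m, g.depth_m, g.thickness_m,
                            g.nx, g.ny, g.nz_per_layer, g.layer_fractions)
    profile = DepthProfile.linear(g.fluid_fraction_surface, g.fluid_fraction_bone,
                                  g.fibril_density_surface, g.fibril_density_bone)
    center = np.array([g.width_m / 2 + g.width_m * 1e-3, 0.0, g.depth_m / 2])
    if cfg.tissue == "meniscus":
        fib = circumferential_fibril_field(
            mesh, np.array([g.width_m / 2, 0.0, g.depth_m / 2]), profile)
        fib_c = circumferential_fibril_field(
            mesh, np.array([g.width_m / 2, 0.0, g.depth_m / 2]), profile,
            points=mesh.element_centroids())
    else:
        split = assign_split_lines(mesh, center)
        zb = (g.zone_superficial, g.zone_deep)
        fib = build_fibril_field(mesh, split, profile, g.secondary_set_size,
                                 g.primary_fraction, zone_bounds=zb)
        fib_c = build_fibril_field(mesh, split, profile, g.secondary_set_size,
                                   g.primary_fraction, zone_bounds=zb,
                                   points=mesh.element_centroids())
    return mesh, fib, fib_c


def archetype_from_config(cfg: RunConfig, label: str, seed: int) -> SubjectArchetype:
    ld = cfg.loading
    if label == "healthy":
        return healthy_archetype(
            seed=seed, body_weight_N=ld.body_weight_N,
            peak1_bw=ld.healthy_peak1_bw, peak2_bw=ld.healthy_peak2_bw,
            noise_rel=ld.noise_rel)
    if label == "koa":
        return koa_archetype(
            seed=seed, body_weight_N=ld.body_weight_N,
            peak1_bw=ld.healthy_peak1_bw * ld.koa_force_gain,
            peak2_bw=ld.healthy_peak2_bw * ld.koa_force_gain,
            adduction_scale=ld.koa_adduction_scale,
            cop_shift_lat_mm=ld.koa_cop_shift_lat_mm,
            cop_shift_med_mm=ld.koa_cop_shift_med_mm,
            noise_rel=ld.noise_rel)
    raise ValueError(f"unknown archetype label {label!r}")


def _solver_config(cfg: RunConfig) -> SolverConfig:
    s = cfg.solver
    return SolverConfig(
        rtol=s.rtol, max_iter=s.max_iter, penalty=s.penalty_Pa_per_m,
        force_tol=s.force_tol, max_halvings=s.max_halvings,
        stab_beta=s.stab_beta, step_cap=s.step_cap,
        contact_reg=s.contact_reg_m, contact_edge_band=s.contact_edge_band_m,
        pressure_smoothing=s.pressure_smoothing)


def _indenter(cfg: RunConfig) -> RigidIndenter:
    """Condyle-like spherical indenter by default; flat punch on request."""
    g = cfg.geometry
    hw = cfg.loading.indenter_half_width_m
    return RigidIndenter(
        center=[g.width_m / 2, 0.0, g.depth_m / 2],
        normal=[0.0, -1.0, 0.0], axis1=[1.0, 0.0, 0.0], axis2=[0.0, 0.0, 1.0],
        shape=cfg.loading.indenter_shape,
        radius=cfg.loading.indenter_radius_m,
        half_widths=(hw, hw), control="force")


# ---------------------------------------------------------------- results


@dataclass
class CompartmentResult:
    compartment: str
    history: SolutionHistory
    series: dict                      # metric -> StanceSeries
    peak_stats: dict                  # metric -> SummaryStats at peak force
    exceedance: dict                  # metric -> ExceedanceReport at peak force
    cop_at_peak: np.ndarray           # (3,) m
    retained_fraction: float
    peak_index: int


@dataclass
class RunResult:
    label: str
    config: RunConfig
    compartments: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _metrics_list(cfg: RunConfig) -> list[str]:
    return ["mps"] if cfg.tissue == "meniscus" else ["mss", "sfd"]


def run_subject(cfg: RunConfig, label: str, out_dir=None) -> RunResult:
    """Run one archetype through all configured compartments.

    Artifacts per compartment: loading CSV, per-step summary CSVs per
    metric, per-element metric fields (long CSV), optional VTK of the
    final state; plus a run manifest.
    """
    t_start = time.time()
    out = Path(out_dir if out_dir is not None else cfg.out_dir) / label
    out.mkdir(parents=True, exist_ok=True)
    mesh, fib, fib_c = build_plug(cfg)
    params = _material_from_config(cfg)
    scfg = _solver_config(cfg)
    ind = _indenter(cfg)
    seed = (cfg.seed * 1000003 + (17 if label == "koa" else 5)) % (2**31 - 1)
    arch = archetype_from_config(cfg, label, seed)
    profile = generate_stance_profile(arch, cfg.loading.n_samples)
    write_profile_csv(profile, out / "loading_profile.csv")

    thresholds = {"mss": cfg.metrics.mss_threshold_pct,
                  "sfd": cfg.metrics.sfd_threshold_pct,
                  "mps": cfg.metrics.mss_threshold_pct}

    result = RunResult(label=label, config=cfg)
    conv = {}
    for comp in cfg.compartments:
        split = MediolateralSplit.constant(cfg.loading.medial_split,
                                           cfg.loading.n_samples)
        sched = map_profile_to_schedule(
            profile, comp, split, mesh, ind,
            stance_duration_s=cfg.stance_duration_s,
            force_scale=cfg.loading.force_scale,
            nominal_contact_area_m2=cfg.loading.nominal_contact_area_m2,
            tilt_per_Nm=cfg.loading.tilt_per_Nm if cfg.loading.use_tilt else 0.0)
        if not cfg.loading.use_cop_offset:
            sched.indenter_offset = np.zeros_like(sched.indenter_offset)
        # explant-like plug: bone-fixed base, free and draining lateral
        # faces, drainage through the articular surface outside the contact
        bcs = [
            BoundaryCondition("displacement", "bottom", 0.0),
            BoundaryCondition("pressure", "articular", 0.0),
            BoundaryCondition("pressure", "lateral", 0.0),
        ]
        logger.info("[%s/%s] solving %d stance steps", label, comp, sched.n_steps)
        hist = solve_transient(mesh, fib, params, sched, bcs, indenter=ind,
                               config=scfg)
        conv[comp] = {
            "steps": len(hist.records),
            "total_newton_iters": int(sum(r.newton_iters for r in hist.records)),
            "halvings": int(sum(c["halvings"] for c in hist.convergence_log)),
        }
        result.compartments[comp] = _evaluate_compartment(
            cfg, comp, mesh, fib_c, hist, thresholds, out)

    result.manifest = {
        "package_version": __version__,
        "label": label,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "archetype_seed": seed,
        "coordinate_frame": "x anterior-posterior, y superior-inferior (depth -y), z medial-lateral",
        "python": platform.python_version(),
        "convergence": conv,
        "wall_time_s": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=1, sort_keys=True)
    return result


def _evaluate_compartment(cfg, comp, mesh, fib_c, hist, thresholds, out: Path,
                          step_masks=None):
    mcfg = cfg.metrics
    if mcfg.filter == "footprint":
        # margin of half an in-plane element spacing so the patch always
        # captures the centroids it loads, even on coarse meshes
        g = cfg.geometry
        margin = 0.5 * max(g.width_m / g.nx, g.depth_m / g.ny)
        mask = footprint_union_mask(hist, margin=margin)
        # per-step instantaneous contact patches: strains at any instant
        # localise under the current patch, and comparing subjects on their
        # own union footprints would dilute a shifted-contact subject
        step_masks = [footprint_step_weights(mesh, r, hist.indenter, margin)
                      for r in hist.records]
    elif mcfg.filter == "none":
        mask = None
    else:
        mask = None   # strain-floor applied per metric below
    prim_c = fib_c.directions[:, 0, :]

    series, peak_stats, exceed = {}, {}, {}
    rows = []
    for metric in _metrics_list(cfg):
        ss = stance_series(hist, metric, fibril_dirs=prim_c, filter_mask=mask,
                           step_masks=step_masks if mcfg.filter == "footprint" else None)
        series[metric] = ss
        pk = ss.peak_index
        Fpk = hist.records[pk].F_centroid
        vals = metric_from_F(Fpk, metric, prim_c)
        f = MetricField(values=vals, volumes=mesh.element_volume,
                        centroids=mesh.element_centroids())
        if mcfg.filter == "footprint":
            wts = step_masks[pk]
            if np.any(wts > 0):
                sel = wts > 0.0
                f = MetricField(values=vals[sel],
                                volumes=(mesh.element_volume * wts)[sel],
                                centroids=mesh.element_centroids()[sel])
                f.retained_fraction = float(
                    (mesh.element_volume * wts).sum() / mesh.element_volume.sum())
            else:
                f = contact_volume_filter(f, "footprint", footprint_mask=mask)
        elif mcfg.filter == "strain-floor":
            peaks = np.max([metric_from_F(r.F_centroid, metric, prim_c)
                            for r in hist.records], axis=0)
            f = contact_volume_filter(f, "strain-floor",
                                      strain_floor_pct=mcfg.strain_floor_pct,
                                      peak_values=peaks)
        peak_stats[metric] = volume_weighted_percentiles(f)
        exceed[metric] = exceedance_fraction(f, thresholds[metric])
        arr = ss.as_arrays()
        df = pd.DataFrame(arr)
        df.insert(0, "stance_pct", 100.0 * arr["time_s"] / arr["time_s"][-1])
        df.to_csv(out / f"summary_{metric}_{comp}.csv", index=False,
                  float_format="%.10g")
        for si, rec in enumerate(hist.records):
            v = metric_from_F(rec.F_centroid, metric, prim_c)
            rows.append(pd.DataFrame({
                "step": si, "metric": metric, "element": np.arange(mesh.n_elements),
                "value_pct": v, "volume_m3": mesh.element_volume,
            }))
    if cfg.output.write_fields_csv:
        pd.concat(rows, ignore_index=True).to_csv(
            out / f"metric_fields_{comp}.csv", index=False, float_format="%.10g")

    ref = series[_metrics_list(cfg)[0]]
    cop_df = pd.DataFrame({
        "time_s": ref.cop.times,
        "cop_x_m": ref.cop.positions[:, 0],
        "cop_y_m": ref.cop.positions[:, 1],
        "cop_z_m": ref.cop.positions[:, 2],
        "force_N": ref.cop.total_force,
    })
    cop_df.to_csv(out / f"cop_{comp}.csv", index=False, float_format="%.10g")

    if cfg.output.write_vtk:
        from .vtk_io import write_vtk
        rec = hist.records[ref.peak_index]
        cell = {m: metric_from_F(rec.F_centroid, m, prim_c)
                for m in _metrics_list(cfg)}
        write_vtk(out / f"peak_state_{comp}.vtk", mesh,
                  point_data={"displacement": rec.u, "pore_pressure": rec.p},
                  cell_data=cell)

    retained = getattr(
        contact_volume_filter(
            MetricField(values=np.zeros(mesh.n_elements) + 1.0,
                        volumes=mesh.element_volume),
            "footprint", footprint_mask=mask) if mask is not None else None,
        "retained_fraction", 1.0)
    return CompartmentResult(
        compartment=comp, history=hist, series=series, peak_stats=peak_stats,
        exceedance=exceed,
        cop_at_peak=ref.cop.positions[ref.peak_index],
        retained_fraction=retained, peak_index=ref.peak_index)


# ---------------------------------------------------------------- compare


@dataclass
class ComparisonReport:
    """Aligned healthy-vs-KOA summary; differences are KOA minus healthy."""

    compartments: list
    metrics: list
    peak: dict          # (comp, metric) -> {healthy: stats, koa: stats, diff_pp}
    exceedance: dict    # (comp, metric) -> {healthy, koa} fractions
    cop_shift_mm: dict  # comp -> posterior(+) shift of KOA vs healthy at peak
    series: dict        # (comp, metric) -> DataFrame with both subjects

    def to_json_dict(self) -> dict:
        out = {"compartments": self.compartments, "metrics": self.metrics,
               "peak": {}, "exceedance": {}, "cop_shift_mm": self.cop_shift_mm}
        for (c, m), d in self.peak.items():
            out["peak"][f"{c}:{m}"] = {
                "healthy_median_pct": d["healthy"].median,
                "koa_median_pct": d["koa"].median,
                "median_diff_pp": d["diff_pp"],
                "healthy_q25_pct": d["healthy"].q25,
                "healthy_q75_pct": d["healthy"].q75,
                "koa_q25_pct": d["koa"].q25,
                "koa_q75_pct": d["koa"].q75,
            }
        for (c, m), d in self.exceedance.items():
            out["exceedance"][f"{c}:{m}"] = d
        return out


def compare_subjects(healthy: RunResult, koa: RunResult) -> ComparisonReport:
    """Build the healthy-vs-KOA comparison from two completed runs."""
    if config_hash(healthy.config) != config_hash(koa.config):
        diffs = [k for k in healthy.config.model_dump()
                 if healthy.config.model_dump()[k] != koa.config.model_dump()[k]]
        raise ValueError(f"runs were made with different configs; differing "
                         f"block(s): {', '.join(diffs)}")
    comps = list(healthy.compartments)
    mets = _metrics_list(healthy.config)
    peak, exc, cop_shift, series = {}, {}, {}, {}
    for c in comps:
        h = healthy.compartments[c]
        k = koa.compartments[c]
        for m in mets:
            hs, ks = h.peak_stats[m], k.peak_stats[m]
            peak[(c, m)] = {"healthy": hs, "koa": ks,
                            "diff_pp": ks.median - hs.median}
            exc[(c, m)] = {"healthy": h.exceedance[m].exceeding_fraction,
                           "koa": k.exceedance[m].exceeding_fraction}
            ha, ka = h.series[m].as_arrays(), k.series[m].as_arrays()
            series[(c, m)] = pd.DataFrame({
                "time_s": ha["time_s"],
                "healthy_median": ha["median"], "koa_median": ka["median"],
                "healthy_q75": ha["q75"], "koa_q75": ka["q75"],
            })
        # posterior = -x; report posterior shift as positive
        dx = k.cop_at_peak[0] - h.cop_at_peak[0]
        cop_shift[c] = float(-dx * 1e3)
    return ComparisonReport(compartments=comps, metrics=mets, peak=peak,
                            exceedance=exc, cop_shift_mm=cop_shift, series=series)


def write_comparison(report: ComparisonReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "comparison.json", "w") as f:
        json.dump(report.to_json_dict(), f, indent=1, sort_keys=True)
    for (c, m), df in report.series.items():
        df.to_csv(out / f"series_{m}_{c}.csv", index=False, float_format="%.10g")
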