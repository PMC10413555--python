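"""Mechanoregulatory strain metrics and volume-weighted field statistics.

Three tissue-level strain measures drive the analysis:

* MSS — maximum shear strain: the largest pairwise difference of the
  principal values of the Green-Lagrange strain tensor
  E = (F^T F - I)/2.  Elevated MSS (threshold 30%) is associated with
  proteoglycan depletion.
* SFD — strain in the fibril direction: the logarithmic stretch
  ln |F e_f| along the local collagen direction.  Elevated SFD
  (threshold 10%) is associated with collagen degradation.
* MPS — maximum principal strain of the spatial logarithmic (Hencky)
  strain tensor ln V, V = (F F^T)^(1/2); the meniscal response measure.

Metrics are evaluated at element centroids and summarised with
volume-weighted statistics (quartiles, exceedance fractions), optionally
restricted to the cartilage volume under the contact footprint.  Strains
are reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import fibril_strain
from .fe import SolutionHistory

__all__ = [
    "PrincipalStrains",
    "MetricField",
    "SummaryStats",
    "ExceedanceReport",
    "COPTrace",
    "principal_green_lagrange",
    "max_shear_strain",
    "strain_in_fibril_direction",
    "max_principal_log_strain",
    "metric_from_F",
    "contact_volume_filter",
    "volume_weighted_percentiles",
    "exceedance_fraction",
    "center_of_pressure",
    "cop_from_nodal_forces",
    "stance_series",
    "MSS_THRESHOLD_PCT",
    "SFD_THRESHOLD_PCT",
]

# degeneration thresholds (strain %): shear -> proteoglycan depletion,
# fibril strain -> collagen degradation
MSS_THRESHOLD_PCT = 30.0
SFD_THRESHOLD_PCT = 10.0


@dataclass
class PrincipalStrains:
    """Sorted (descending) principal Green-Lagrange strains."""

    values: np.ndarray  # (..., 3), descending along the last axis

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[-1] != 3 or np.any(np.diff(v, axis=-1) > 1e-12):
            raise ValueError("principal strains must be sorted descending")
        self.values = v


def principal_green_lagrange(F: np.ndarray) -> PrincipalStrains:
    """Principal values of E = (F^T F - I)/2, sorted descending.

    Accepts a single 3x3 tensor or a batch (..., 3, 3).
    """
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ji,...jk->...ik", F, F)
    E = 0.5 * (C - np.eye(3))
    ev = np.linalg.eigvalsh(E)          # ascending
    return PrincipalStrains(ev[..., ::-1])


def max_shear_strain(p: PrincipalStrains | np.ndarray) -> np.ndarray | float:
    """Largest pairwise difference of principal Green-Lagrange strains.

    For sorted input this equals eps_1 - eps_3; the absolute-value form
    over all three pairs is evaluated explicitly.
    """
    v = p.values if isinstance(p, PrincipalStrains) else np.asarray(p, dtype=float)
    d = np.stack([
        np.abs(v[..., 0] - v[..., 1]),
        np.abs(v[..., 0] - v[..., 2]),
        np.abs(v[..., 1] - v[..., 2]),
    ], axis=-1)
    out = d.max(axis=-1)
    return float(out) if out.ndim == 0 else out


def strain_in_fibril_direction(F: np.ndarray, e_f: np.ndarray) -> float:
    """Logarithmic stretch along the fibril, ln |F e_f| (single source of truth)."""
    return fibril_strain(F, e_f)


def _sfd_batch(F: np.ndarray, e_f: np.ndarray) -> np.ndarray:
    Fe = np.einsum("...ij,...j->...i", F, e_f)
    return np.log(np.linalg.norm(Fe, axis=-1))


def max_principal_log_strain(F: np.ndarray) -> np.ndarray | float:
    """Largest eigenvalue of the spatial Hencky strain ln V, V = (F F^T)^(1/2)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    B = np.einsum("...ij,...kj->...ik", F, F)
    lam = np.linalg.eigvalsh(B)[..., -1]
    out = 0.5 * np.log(lam)
    return float(out) if out.ndim == 0 else out


@dataclass
class MetricField:
    """Per-element metric values (%) with volumes and optional region labels."""

    values: np.ndarray                  # (E,) metric in percent
    volumes: np.ndarray                 # (E,) m^3
    centroids: np.ndarray | None = None  # (E, 3)
    region: np.ndarray | None = None     # (E,) labels

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.values.shape != self.volumes.shape:
            raise ValueError("values and volumes must have matching shape")
        if np.any(self.volumes <= 0):
            raise ValueError("element volumes must be positive")


@dataclass
class SummaryStats:
    """Volume-weighted distribution summary of a metric field (all in %)."""

    q25: float
    median: float
    q75: float
    minimum: float
    maximum: float
    retained_volume_fraction: float = 1.0

    def __post_init__(self):
        if not (self.q25 <= self.median <= self.q75 + 1e-12):
            raise ValueError("quartiles out of order")


@dataclass
class ExceedanceReport:
    threshold_pct: float
    exceeding_volume: float       # m^3
    exceeding_fraction: float     # of retained volume

    def __post_init__(self):
        if not (0.0 <= self.exceeding_fraction <= 1.0):
            raise ValueError("exceeding fraction must lie in [0, 1]")


@dataclass
class COPTrace:
    """Centre-of-pressure positions per step (m); NaN rows when unloaded."""

    times: np.ndarray
    positions: np.ndarray   # (n_steps, 3)
    total_force: np.ndarray  # (n_steps,)


def metric_from_F(F: np.ndarray, metric: str, fibril_dirs: np.ndarray | None = None) -> np.ndarray:
    """Batched metric evaluation (values in %, not fractions).

    ``metric`` is one of 'mss', 'sfd', 'mps'; 'sfd' needs per-point
    fibril directions of matching batch shape.
    """
    m = metric.lower()
    if m == "mss":
        return 100.0 * max_shear_strain(principal_green_lagrange(F))
    if m == "sfd":
        if fibril_dirs is None:
            raise ValueError("SFD needs fibril directions")
        return 100.0 * _sfd_batch(F, fibril_dirs)
    if m == "mps":
        return 100.0 * max_principal_log_strain(F)
    raise ValueError(f"unknown metric {metric!r}")


def contact_volume_filter(
    fieldv: MetricField,
    criterion: str = "footprint",
    footprint_mask: np.ndarray | None = None,
    strain_floor_pct: float = 1.0,
    peak_values: np.ndarray | None = None,
) -> MetricField:
    """Restrict a metric field to the tissue volume engaged by contact.

    'footprint': keep elements flagged by ``footprint_mask`` (union of the
    indenter footprints over the stance, projected through the depth).
    'strain-floor': keep elements whose peak metric over the stance
    (``peak_values``, defaults to the field's own values) exceeds
    ``strain_floor_pct``.

    The retained volume fraction is reported on the filtered field; the
    fraction observed for a given model is a result, never a target.
    """
    if fieldv.values.size == 0:
        raise ValueError("empty metric field")
    if criterion == "footprint":
        if footprint_mask is None:
            raise ValueError("footprint criterion needs a footprint mask")
        keep = np.asarray(footprint_mask, dtype=bool)
    elif criterion == "strain-floor":
        pv = fieldv.values if peak_values is None else np.asarray(peak_values)
        keep = pv > strain_floor_pct
    else:
        raise ValueError(f"unknown filter criterion {criterion!r}")
    if not np.any(keep):
        raise ValueError(
            "contact-volume filter retained no elements; relax the footprint "
            "or lower the strain floor")
    frac = float(fieldv.volumes[keep].sum() / fieldv.volumes.sum())
    out = MetricField(
        values=fieldv.values[keep],
        volumes=fieldv.volumes[keep],
        centroids=None if fieldv.centroids is None else fieldv.centroids[keep],
        region=None if fieldv.region is None else fieldv.region[keep],
    )
    out.retained_fraction = frac
    return out


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Volume-weighted quantile, averaged-inverted-CDF convention.

    Equals ``numpy.percentile(repeat(values, weights), method=
    'averaged_inverted_cdf')`` exactly when the weights are integers: the
    target mass q*W falling strictly inside a value's weight block returns
    that value; exactly on a block boundary, the mean of the two adjacent
    values.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    W = cw[-1]
    h = q * W
    tol = 1e-9 * W
    i = int(np.searchsorted(cw, h - tol, side="left"))
    i = min(i, v.size - 1)
    if i + 1 < v.size and abs(cw[i] - h) <= tol:
        # midpoint written exactly as the replication convention evaluates it
        return float(v[i + 1] - 0.5 * (v[i + 1] - v[i]))
    return float(v[i])


def volume_weighted_percentiles(fieldv: MetricField, q=(0.25, 0.5, 0.75)) -> SummaryStats:
    """Volume-weighted quartile summary of a metric field."""
    if fieldv.volumes.sum() <= 0:
        raise ValueError("zero total volume")
    for qi in q:
        if not (0.0 < qi < 1.0):
            raise ValueError("quantile fractions must lie in (0, 1)")
    qs = [_weighted_quantile(fieldv.values, fieldv.volumes, qi) for qi in q]
    return SummaryStats(
        q25=qs[0], median=qs[1], q75=qs[2],
        minimum=float(fieldv.values.min()),
        maximum=float(fieldv.values.max()),
        retained_volume_fraction=getattr(fieldv, "retained_fraction", 1.0),
    )


def exceedance_fraction(fieldv: MetricField, threshold_pct: float) -> ExceedanceReport:
    """Volume fraction of the (retained) field exceeding a strain threshold."""
    if not threshold_pct > 0:
        raise ValueError("threshold must be positive")
    over = fieldv.values > threshold_pct
    vol = float(fieldv.volumes[over].sum())
    return ExceedanceReport(
        threshold_pct=threshold_pct,
        exceeding_volume=vol,
        exceeding_fraction=vol / float(fieldv.volumes.sum()),
    )


def center_of_pressure(pressures: np.ndarray, centroids: np.ndarray,
                       areas: np.ndarray) -> np.ndarray:
    """Pressure-weighted centroid: COP = sum(p A x) / sum(p A).

    Returns NaNs when the total normal force vanishes.
    """
    pA = np.asarray(pressures, dtype=float) * np.asarray(areas, dtype=float)
    total = pA.sum()
    if total <= 0.0:
        return np.full(3, np.nan)
    return (pA[:, None] * np.asarray(centroids, dtype=float)).sum(axis=0) / total


def cop_from_nodal_forces(nodes_xyz: np.ndarray, forces: np.ndarray,
                          normal: np.ndarray) -> np.ndarray:
    """COP of nodal contact forces, weighted by the normal force component."""
    fn = np.asarray(forces, dtype=float) @ np.asarray(normal, dtype=float)
    total = fn.sum()
    if total <= 0.0:
        return np.full(3, np.nan)
    return (fn[:, None] * np.asarray(nodes_xyz, dtype=float)).sum(axis=0) / total


@dataclass
class StanceSeries:
    """Per-step volume-weighted summaries of one metric over the stance."""

    times: np.ndarray
    stats: list[SummaryStats]
    peak_index: int                     # step of peak contact force
    cop: COPTrace | None = None

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "time_s": self.times,
            "q25": np.array([s.q25 for s in self.stats]),
            "median": np.array([s.median for s in self.stats]),
            "q75": np.array([s.q75 for s in self.stats]),
            "max": np.array([s.maximum for s in self.stats]),
        }


def footprint_step_mask(mesh, rec, indenter, margin: float = 0.0) -> np.ndarray:
    """Per-element mask of one step's contact patch (flat rect / sphere disc).

    Element centroids are projected along the depth axis onto the articular
    plane and tested against the footprint at the step's indenter pose; for
    spheres the patch radius follows from the indentation depth.
    """
    cent = mesh.element_centroids()
    if rec.indenter_pose is None or rec.total_contact_force <= 0.0:
        return np.zeros(mesh.n_elements, dtype=bool)
    q0, a1, a2, n = rec.indenter_pose
    w = cent - q0
    if indenter is not None and indenter.shape == "flat":
        hw1, hw2 = indenter.half_widths
        return (np.abs(w @ a1) <= hw1 + margin) & (np.abs(w @ a2) <= hw2 + margin)
    if indenter is not None:
        d = max(rec.indenter_depth, 0.0)
        a = np.sqrt(max(2.0 * indenter.radius * d - d * d, 0.0))
        lat = w - np.outer(w @ n, n)
        return np.linalg.norm(lat, axis=1) <= a + margin
    if rec.contact_nodes.size:
        pts = mesh.nodes[rec.contact_nodes] - q0
        lo = (pts @ a1).min() - margin
        hi = (pts @ a1).max() + margin
        return ((w @ a1) >= lo) & ((w @ a1) <= hi)
    return np.zeros(mesh.n_elements, dtype=bool)


def footprint_step_weights(mesh, rec, indenter, margin: float = 0.0) -> np.ndarray:
    """Smooth per-element contact-volume weights for one step, in [0, 1].

    A quadratic window over the contact patch replaces the hard in/out
    mask: on meshes whose element spacing is comparable to the patch size
    a hard mask quantises the retained set and makes the summary
    statistics jump with patch position.  Elements well inside the patch
    get weight 1, the weight falls to 0 one ``margin`` beyond the patch
    boundary.
    """
    cent = mesh.element_centroids()
    if rec.indenter_pose is None or rec.total_contact_force <= 0.0:
        return np.zeros(mesh.n_elements)
    q0, a1, a2, n = rec.indenter_pose
    w = cent - q0
    if indenter is not None and indenter.shape == "flat":
        hw1, hw2 = indenter.half_widths
        s1 = np.clip(((hw1 + margin) - np.abs(w @ a1)) / max(margin, 1e-12), 0.0, 1.0)
        s2 = np.clip(((hw2 + margin) - np.abs(w @ a2)) / max(margin, 1e-12), 0.0, 1.0)
        return s1 * s2
    d = max(rec.indenter_depth, 0.0)
    a = np.sqrt(max(2.0 * (indenter.radius if indenter else 0.0) * d - d * d, 0.0))
    lat = np.linalg.norm(w - np.outer(w @ n, n), axis=1)
    return np.clip(((a + margin) - lat) / max(margin, 1e-12), 0.0, 1.0)


def footprint_union_mask(history: SolutionHistory, margin: float = 0.0) -> np.ndarray:
    """Union of the per-step contact-patch masks over all loaded steps."""
    mesh = history.mesh
    keep = np.zeros(mesh.n_elements, dtype=bool)
    ind = getattr(history, "indenter", None)
    any_contact = False
    for rec in history.records:
        m = footprint_step_mask(mesh, rec, ind, margin)
        if m.any():
            any_contact = True
            keep |= m
    if not any_contact:
        keep[:] = True
    return keep


def stance_series(
    history: SolutionHistory,
    metric: str,
    fibril_dirs: np.ndarray | None = None,
    filter_mask: np.ndarray | None = None,
    step_masks: list | None = None,
) -> StanceSeries:
    """Metric summaries at every stance step, on centroid deformation gradients.

    ``filter_mask`` restricts to a fixed subset of elements (e.g. the
    contact footprint union); ``step_masks`` instead applies one mask or
    smooth weight array per step (the instantaneous contact patch),
    falling back to ``filter_mask`` on unloaded steps.  Also computes the
    contact COP trace and flags the peak-contact-force step.
    """
    if not history.records:
        raise ValueError("empty solution history")
    mesh = history.mesh
    vols = mesh.element_volume
    base = np.ones(mesh.n_elements, dtype=bool) if filter_mask is None else filter_mask

    stats = []
    cops = []
    forces = []
    for si, rec in enumerate(history.records):
        vals = metric_from_F(rec.F_centroid, metric, fibril_dirs)
        wts = None
        if step_masks is not None and step_masks[si] is not None:
            m = np.asarray(step_masks[si], dtype=float)
            if m.sum() > 0:
                wts = m
        if wts is not None:
            sel = wts > 0.0
            f = MetricField(values=vals[sel], volumes=(vols * wts)[sel],
                            centroids=mesh.element_centroids()[sel])
            f.retained_fraction = float((vols * wts).sum() / vols.sum())
        else:
            f = MetricField(values=vals[base], volumes=vols[base],
                            centroids=mesh.element_centroids()[base])
            f.retained_fraction = float(vols[base].sum() / vols.sum())
        stats.append(volume_weighted_percentiles(f))
        forces.append(rec.total_contact_force)
        if rec.contact_nodes.size:
            x = mesh.nodes[rec.contact_nodes] + rec.u[rec.contact_nodes]
            normal = rec.indenter_pose[3] if rec.indenter_pose else -mesh.depth_axis
            cops.append(cop_from_nodal_forces(x, rec.contact_forces, normal))
        else:
            cops.append(np.full(3, np.nan))
    forces = np.asarray(forces)
    times = history.times
    return StanceSeries(
        times=times,
        stats=stats,
        peak_index=int(np.argmax(forces)) if np.any(forces > 0) else int(len(stats) - 1),
        cop=COPTrace(times=times, positions=np.asarray(cops), total_force=forces),
    )
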