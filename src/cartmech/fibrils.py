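"""Collagen architecture: depth profiles, split lines and the Benninghoff arcade.

Articular cartilage collagen runs parallel to the surface superficially
(along "split lines" that point toward the compartment's centre of area),
arches through the middle zone, and ends perpendicular to the surface in
the deep zone.  Fibril density and fluid fraction vary with depth.  This
module builds per-integration-point fibril direction/weight fields on a
plug mesh: one primary (arcade) direction plus a quasi-uniform secondary
direction set sharing the remaining fibril density.

All direction fields are constructed from the local geometric frame
(split-line direction, surface normal), so rigidly rotating the mesh and
the split-line centre rotates every fibril direction by the same rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .mesh import Mesh, gauss_points_3d, hex_shape_functions

__all__ = [
    "DepthProfile",
    "SplitLineField",
    "FibrilField",
    "assign_split_lines",
    "benninghoff_orientation",
    "build_fibril_field",
    "circumferential_fibril_field",
    "secondary_direction_set",
]


@dataclass
class DepthProfile:
    """Depth-dependent composition, on normalised depth z_hat in [0, 1].

    z_hat = 0 at the articular surface, 1 at the bone interface.  Defaults
    are canonical linear profiles from the fibril-reinforced cartilage
    modelling literature: fluid fraction 0.90 - 0.20 z_hat, relative fibril
    density 0.35 - 0.20 z_hat.
    """

    fluid_fraction: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    fibril_density: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fluid_fraction is None:
            self.fluid_fraction = lambda z: 0.90 - 0.20 * np.asarray(z)
        if self.fibril_density is None:
            self.fibril_density = lambda z: 0.35 - 0.20 * np.asarray(z)

    @classmethod
    def linear(cls, ff_surface: float = 0.90, ff_bone: float = 0.70,
               fd_surface: float = 0.35, fd_bone: float = 0.15) -> "DepthProfile":
        return cls(
            fluid_fraction=lambda z: ff_surface + (ff_bone - ff_surface) * np.asarray(z),
            fibril_density=lambda z: fd_surface + (fd_bone - fd_surface) * np.asarray(z),
        )

    def validate(self, z: np.ndarray) -> None:
        ff = np.asarray(self.fluid_fraction(z))
        if np.any(ff <= 0.0) or np.any(ff >= 1.0):
            raise ValueError("fluid_fraction must lie strictly inside (0, 1) at all sampled depths")
        if np.any(np.asarray(self.fibril_density(z)) < 0.0):
            raise ValueError("fibril_density must be non-negative at all sampled depths")


@dataclass
class SplitLineField:
    """Superficial collagen directions on the articular surface.

    Per articular-surface node: an in-plane unit vector pointing toward the
    compartment centre of area.  ``center`` and the surface normal are kept
    so the same rule can be evaluated at arbitrary surface-projected points
    (element centroids, Gauss points).
    """

    node_indices: np.ndarray          # (S,) articular surface node ids
    directions: np.ndarray            # (S, 3) unit tangent vectors
    center: np.ndarray                # (3,) centre of area
    surface_normal: np.ndarray        # (3,) outward unit normal
    fallback: np.ndarray              # (3,) unit tangent used at degenerate points

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Split-line direction at arbitrary points (projected to the surface)."""
        return _split_directions(np.atleast_2d(points), self.center,
                                 self.surface_normal, self.fallback, warn=False)


def _split_directions(points: np.ndarray, center: np.ndarray, normal: np.ndarray,
                      fallback: np.ndarray, warn: bool) -> np.ndarray:
    v = center[None, :] - points
    v = v - (v @ normal)[:, None] * normal[None, :]
    n = np.linalg.norm(v, axis=1)
    degenerate = n < 1e-12
    if np.any(degenerate):
        if warn:
            warnings.warn(
                f"{int(degenerate.sum())} surface point(s) coincide with the "
                "split-line centre projection; falling back to the +x tangent",
                stacklevel=3,
            )
        v[degenerate] = fallback
        n[degenerate] = 1.0
    return v / n[:, None]


def assign_split_lines(mesh: Mesh, center: np.ndarray) -> SplitLineField:
    """Split-line field: unit tangent projection of (center - point) per surface node.

    ``center`` must lie on or above the articular surface plane (i.e. not
    inside the tissue).
    """
    center = np.asarray(center, dtype=float)
    normal = -mesh.depth_axis  # outward
    if (center - mesh.surface_point) @ mesh.depth_axis > 1e-12:
        raise ValueError("split-line center must lie on or above the articular surface plane")
    # deterministic fallback tangent: global +x projected to the surface
    fx = np.array([1.0, 0.0, 0.0])
    fx = fx - (fx @ normal) * normal
    if np.linalg.norm(fx) < 1e-12:
        fx = np.array([0.0, 0.0, 1.0])
        fx = fx - (fx @ normal) * normal
    fx = fx / np.linalg.norm(fx)

    nodes = mesh.node_set("articular")
    dirs = _split_directions(mesh.nodes[nodes], center, normal, fx, warn=True)
    return SplitLineField(node_indices=nodes, directions=dirs, center=center,
                          surface_normal=normal, fallback=fx)


def benninghoff_orientation(z_hat, surface_dir, zone_bounds=(0.1, 0.5)) -> np.ndarray:
    """Primary fibril direction at normalised depth, in the local surface frame.

    The local frame is (e1, e2, e3) with e1, e2 spanning the articular
    surface and e3 the outward normal.  ``surface_dir`` is the in-plane
    split-line direction as a 2-vector (components on e1, e2).  Above the
    superficial bound z_s the fibril lies in-plane along ``surface_dir``;
    below the deep bound z_d it runs along the inward normal (0, 0, -1);
    between, it rotates in the plane spanned by the two with the arcade
    angle linear in depth (monotone surface -> deep).

    Accepts scalar or array ``z_hat`` (broadcasting over leading axes of
    ``surface_dir`` of shape (..., 2)); returns unit 3-vectors (..., 3).
    """
    zs, zd = zone_bounds
    if not (0.0 < zs < zd < 1.0):
        raise ValueError(f"zone_bounds must satisfy 0 < z_s < z_d < 1, got ({zs}, {zd})")
    z = np.asarray(z_hat, dtype=float)
    if np.any(z < 0.0) or np.any(z > 1.0):
        raise ValueError("z_hat must lie in [0, 1]")
    sd = np.asarray(surface_dir, dtype=float)
    nrm = np.linalg.norm(sd, axis=-1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise ValueError("surface_dir must be a nonzero in-plane vector")
    sd = sd / nrm
    theta = np.clip((z - zs) / (zd - zs), 0.0, 1.0) * (np.pi / 2.0)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty(np.broadcast_shapes(z.shape, sd.shape[:-1]) + (3,))
    out[..., 0] = c * sd[..., 0]
    out[..., 1] = c * sd[..., 1]
    out[..., 2] = -s
    return out


def secondary_direction_set(size: int = 13) -> np.ndarray:
    """Quasi-uniform set of unit directions (axes) for secondary fibrils.

    The default 13-direction set is the classical cube-axes family: 3 edge
    axes <100>, 4 body diagonals <111> and 6 face diagonals <110>, which is
    the standard secondary-fibril arrangement in fibril-reinforced cartilage
    models.  Other sizes use a deterministic Fibonacci hemisphere.
    """
    if size == 0:
        return np.zeros((0, 3))
    if size == 13:
        dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                (1, 1, 1), (-1, 1, 1), (1, -1, 1), (1, 1, -1),
                (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)]
        d = np.asarray(dirs, dtype=float)
    else:
        i = np.arange(size, dtype=float)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        zc = (i + 0.5) / size  # hemisphere
        r = np.sqrt(1.0 - zc**2)
        d = np.stack([r * np.cos(phi), r * np.sin(phi), zc], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class FibrilField:
    """Per-point fibril directions and density weights.

    ``directions[p, 0]`` is the primary (arcade) direction; the remaining
    ``directions[p, 1:]`` are the secondary set.  ``weights[p]`` partitions
    the point's total fibril density between all directions.
    """

    points: np.ndarray        # (P, 3) evaluation points
    z_hat: np.ndarray         # (P,) normalised depths
    directions: np.ndarray    # (P, D, 3) unit vectors
    weights: np.ndarray       # (P, D) non-negative, summing to fibril_density(z_hat)
    fluid_fraction: np.ndarray  # (P,) reference fluid fraction at each point

    @property
    def n_directions(self) -> int:
        return self.directions.shape[1]

    def total_density(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def _local_frames(split_dirs: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Orthonormal frames (P, 3, 3) with rows (e1 = split dir, e2 = n x e1, e3 = n)."""
    e1 = split_dirs
    e3 = np.broadcast_to(normal, e1.shape)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1)


def gauss_point_coordinates(mesh: Mesh) -> np.ndarray:
    """Physical coordinates of all 2x2x2 Gauss points, shape (E*8, 3)."""
    pts, _ = gauss_points_3d()
    N = hex_shape_functions(pts)  # (8gp, 8)
    xe = mesh.nodes[mesh.hex_elements]  # (E, 8, 3)
    x = np.einsum("ga,eai->egi", N, xe)
    return x.reshape(-1, 3)


def build_fibril_field(
    mesh: Mesh,
    split: SplitLineField,
    profile: DepthProfile,
    secondary_set_size: int = 13,
    primary_fraction: float = 0.75,
    zone_bounds=(0.1, 0.5),
    points: np.ndarray | None = None,
) -> FibrilField:
    """Populate integration points with arcade + secondary fibril directions.

    ``points`` defaults to all element Gauss points; pass
    ``mesh.element_centroids()`` for a centroid-based field.  The point's
    total fibril density ``profile.fibril_density(z_hat)`` is split between
    the primary direction (share ``primary_fraction``) and the secondary
    set (equal shares of the remainder).
    """
    if not (0.0 < primary_fraction <= 1.0):
        raise ValueError(f"primary_fraction must lie in (0, 1], got {primary_fraction}")
    if secondary_set_size < 0:
        raise ValueError("secondary_set_size must be >= 0")
    if secondary_set_size == 0 and primary_fraction != 1.0:
        primary_fraction = 1.0  # all density is primary when there are no secondaries

    if points is None:
        points = gauss_point_coordinates(mesh)
    points = np.asarray(points, dtype=float)
    z = mesh.normalized_depth(points)
    profile.validate(z)

    sdirs = split.evaluate(points)                      # (P, 3) global tangents
    frames = _local_frames(sdirs, split.surface_normal)  # (P, 3, 3)

    # primary: arcade direction in the local frame, then map to global
    prim_local = benninghoff_orientation(z, np.tile([1.0, 0.0], (points.shape[0], 1)),
                                         zone_bounds)
    primary = np.einsum("pk,pki->pi", prim_local, frames)

    sec_local = secondary_direction_set(secondary_set_size)  # (S, 3)
    secondary = np.einsum("sk,pki->psi", sec_local, frames)  # (P, S, 3)

    directions = np.concatenate([primary[:, None, :], secondary], axis=1)

    rho = np.asarray(profile.fibril_density(z), dtype=float)
    D = directions.shape[1]
    weights = np.empty((points.shape[0], D))
    weights[:, 0] = primary_fraction * rho
    if secondary_set_size > 0:
        weights[:, 1:] = ((1.0 - primary_fraction) * rho / secondary_set_size)[:, None]

    return FibrilField(
        points=points,
        z_hat=z,
        directions=directions,
        weights=weights,
        fluid_fraction=np.asarray(profile.fluid_fraction(z), dtype=float),
    )


def circumferential_fibril_field(
    mesh: Mesh,
    center: np.ndarray,
    profile: DepthProfile,
    secondary_set_size: int = 13,
    primary_fraction: float = 0.75,
    points: np.ndarray | None = None,
) -> FibrilField:
    """Meniscus-style field: primary fibrils run circumferentially.

    The primary direction at each point is tangent to the in-plane circle
    around ``center`` (the dominant collagen orientation of meniscal
    tissue); points on the axis fall back to the +x tangent.  Secondary
    directions and density/fluid profiles follow the same conventions as
    :func:`build_fibril_field`.
    """
    if points is None:
        points = gauss_point_coordinates(mesh)
    points = np.asarray(points, dtype=float)
    z = mesh.normalized_depth(points)
    profile.validate(z)
    normal = -mesh.depth_axis
    radial = points - np.asarray(center, dtype=float)
    radial = radial - (radial @ normal)[:, None] * normal[None, :]
    rn = np.linalg.norm(radial, axis=1)
    deg = rn < 1e-12
    if np.any(deg):
        fx = np.array([1.0, 0.0, 0.0])
        fx = fx - (fx @ normal) * normal
        radial[deg] = fx / np.linalg.norm(fx)
        rn[deg] = 1.0
    radial = radial / rn[:, None]
    circ = np.cross(normal, radial)

    frames = _local_frames(circ, normal)
    sec_local = secondary_direction_set(secondary_set_size)
    secondary = np.einsum("sk,pki->psi", sec_local, frames)
    directions = np.concatenate([circ[:, None, :], secondary], axis=1)

    rho = np.asarray(profile.fibril_density(z), dtype=float)
    if secondary_set_size == 0:
        primary_fraction = 1.0
    D = directions.shape[1]
    weights = np.empty((points.shape[0], D))
    weights[:, 0] = primary_fraction * rho
    if secondary_set_size > 0:
        weights[:, 1:] = ((1.0 - primary_fraction) * rho / secondary_set_size)[:, None]
    return FibrilField(points=points, z_hat=z, directions=directions,
                       weights=weights,
                       fluid_fraction=np.asarray(profile.fluid_fraction(z), dtype=float))
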