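"""Layered hexahedral plug/slab meshes.

The spatial substrate for the tissue model: structured 8-node hexahedral
meshes of cartilage/meniscus plugs with a four-layer depth structure
(two finer superficial layers over two coarser deep layers), named
surface tags (articular, bottom, lateral) and per-element volumes
computed by full Gauss quadrature.

Coordinate convention (joint-like frame): x anterior-posterior,
y superior-inferior, z medial-lateral.  Plug meshes have their articular
surface in the plane y = 0 with the tissue occupying y in [-thickness, 0],
i.e. depth runs along -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Mesh",
    "build_layer_mesh",
    "HEX_FACES",
    "hex_shape_functions",
    "hex_shape_gradients",
    "gauss_points_3d",
]

# Local node coordinates of the VTK/Abaqus 8-node hexahedron.
_XI_NODES = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)

# Local faces (VTK convention), ordered so the right-hand rule gives the
# outward normal.
HEX_FACES = np.array(
    [
        [0, 4, 7, 3],  # xi = -1
        [1, 2, 6, 5],  # xi = +1
        [0, 1, 5, 4],  # eta = -1
        [3, 7, 6, 2],  # eta = +1
        [0, 3, 2, 1],  # zeta = -1
        [4, 5, 6, 7],  # zeta = +1
    ],
    dtype=int,
)


def hex_shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points ``xi`` of shape (..., 3).

    Returns an array of shape (..., 8).
    """
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * _XI_NODES, axis=-1)


def hex_shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Gradients dN_a/dxi at points ``xi`` of shape (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    terms = 1.0 + xi[..., None, :] * _XI_NODES  # (..., 8, 3)
    out = np.empty(xi.shape[:-1] + (8, 3))
    for d in range(3):
        prod = np.ones(xi.shape[:-1] + (8,))
        for e in range(3):
            if e == d:
                prod = prod * _XI_NODES[:, e]
            else:
                prod = prod * terms[..., e]
        out[..., d] = 0.125 * prod
    return out


def gauss_points_3d() -> tuple[np.ndarray, np.ndarray]:
    """Full 2x2x2 Gauss rule on the reference hexahedron: (points (8,3), weights (8,))."""
    g = 1.0 / np.sqrt(3.0)
    pts = _XI_NODES * g
    return pts, np.ones(8)


@dataclass
class Mesh:
    """Hexahedral mesh with layer structure and named surface tags.

    Attributes
    ----------
    nodes : (N, 3) float array, node coordinates in metres.
    hex_elements : (E, 8) int array, VTK-ordered node indices.
    layer_id : (E,) int array, 1 = most superficial layer.
    surface_tags : mapping tag name -> (n_faces, 2) int array of
        (element index, local face index) pairs.
    element_volume : (E,) float array, m^3, by 8-point Gauss quadrature.
    depth_axis : unit vector pointing from the articular surface into the
        tissue (plugs: (0, -1, 0)).
    surface_point : a point on the articular surface plane.
    thickness : tissue thickness in metres (depth normalisation scale).
    """

    nodes: np.ndarray
    hex_elements: np.ndarray
    layer_id: np.ndarray
    surface_tags: dict[str, np.ndarray]
    element_volume: np.ndarray = field(default=None)  # type: ignore[assignment]
    depth_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    surface_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    thickness: float = 1.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.hex_elements = np.asarray(self.hex_elements, dtype=int)
        self.layer_id = np.asarray(self.layer_id, dtype=int)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.surface_point = np.asarray(self.surface_point, dtype=float)
        if self.element_volume is None:
            self.element_volume = self._quadrature_volumes()
        detj = self._det_jacobians()
        if np.any(detj <= 0.0):
            bad = int(np.argwhere(np.any(detj <= 0.0, axis=1))[0, 0])
            raise ValueError(f"element {bad} has non-positive Jacobian")

    # -- geometry helpers -------------------------------------------------

    def _det_jacobians(self) -> np.ndarray:
        pts, _ = gauss_points_3d()
        dN = hex_shape_gradients(pts)  # (8gp, 8, 3)
        xe = self.nodes[self.hex_elements]  # (E, 8, 3)
        # J[e,g,i,k] = d x_i / d xi_k = sum_a dN[g,a,k] * xe[e,a,i]
        J = np.einsum("gak,eai->egik", dN, xe)
        return np.linalg.det(J)  # (E, 8)

    def _quadrature_volumes(self) -> np.ndarray:
        _, w = gauss_points_3d()
        return self._det_jacobians() @ w

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hex_elements.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.hex_elements].mean(axis=1)

    def normalized_depth(self, points: np.ndarray) -> np.ndarray:
        """Normalised depth z_hat in [0, 1]: 0 at the articular surface, 1 at bone."""
        points = np.asarray(points, dtype=float)
        d = (points - self.surface_point) @ self.depth_axis / self.thickness
        return np.clip(d, 0.0, 1.0)

    def face_node_indices(self, tag: str) -> np.ndarray:
        """Node indices (n_faces, 4) of the quad faces in a surface tag."""
        faces = self.surface_tags[tag]
        return self.hex_elements[faces[:, 0][:, None], HEX_FACES[faces[:, 1]]]

    def node_set(self, tag: str) -> np.ndarray:
        """Sorted unique node indices belonging to a surface tag."""
        return np.unique(self.face_node_indices(tag))

    def face_areas_normals(self, tag: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(areas, unit outward normals, centroids) of the faces in a tag."""
        fn = self.face_node_indices(tag)
        p = self.nodes[fn]  # (F, 4, 3)
        # area vector of a (possibly warped) quad = 0.5 * (d1 x d2)
        d1 = p[:, 2] - p[:, 0]
        d2 = p[:, 3] - p[:, 1]
        av = 0.5 * np.cross(d1, d2)
        areas = np.linalg.norm(av, axis=1)
        normals = av / areas[:, None]
        return areas, normals, p.mean(axis=1)

    def nodal_areas(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        """Tributary areas of the nodes of a tagged surface.

        Returns (node indices, areas) with each face's area shared equally
        among its four corner nodes.
        """
        fn = self.face_node_indices(tag)
        areas, _, _ = self.face_areas_normals(tag)
        nodes = np.unique(fn)
        acc = np.zeros(self.n_nodes)
        np.add.at(acc, fn.ravel(), np.repeat(areas / 4.0, 4))
        return nodes, acc[nodes]

    def transform(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "Mesh":
        """Rigidly transformed copy of the mesh (x -> R x + t)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return replace(
            self,
            nodes=self.nodes @ R.T + t,
            hex_elements=self.hex_elements.copy(),
            layer_id=self.layer_id.copy(),
            surface_tags={k: v.copy() for k, v in self.surface_tags.items()},
            element_volume=self.element_volume.copy(),
            depth_axis=R @ self.depth_axis,
            surface_point=R @ self.surface_point + t,
        )


def build_layer_mesh(
    width: float,
    depth: float,
    thickness: float,
    nx: int,
    ny: int,
    nz_per_layer: int,
    layer_thickness_fractions=(0.15, 0.15, 0.35, 0.35),
) -> Mesh:
    """Build a structured layered plug mesh.

    Parameters
    ----------
    width, depth, thickness : plug extents in metres; width along x,
        depth along z, thickness along -y (articular surface at y = 0).
    nx, ny : in-plane element counts along x and z.
    nz_per_layer : through-thickness element count per layer.
    layer_thickness_fractions : per-layer thickness fractions, ordered from
        the articular surface down; must be positive and sum to 1.  The
        default gives four layers with the two superficial layers thinner
        than the two deep layers.
    """
    for name, val in (("width", width), ("depth", depth), ("thickness", thickness)):
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val}")
    for name, val in (("nx", nx), ("ny", ny), ("nz_per_layer", nz_per_layer)):
        if not int(val) >= 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    fr = np.asarray(layer_thickness_fractions, dtype=float)
    if np.any(fr <= 0):
        raise ValueError("layer_thickness_fractions must all be positive")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"layer_thickness_fractions must sum to 1, got sum {fr.sum():g}"
        )

    n_layers = fr.size
    nz = n_layers * nz_per_layer
    # y levels from bottom (-thickness) to top (0); graded by layer fractions
    bounds = -thickness * np.concatenate(([1.0], 1.0 - np.cumsum(fr[::-1])))
    bounds[-1] = 0.0
    ylev = [bounds[0]]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        ylev.extend(np.linspace(b0, b1, nz_per_layer + 1)[1:])
    ylev = np.asarray(ylev)

    xs = np.linspace(0.0, width, nx + 1)
    zs = np.linspace(0.0, depth, ny + 1)

    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    nodes = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    for k, y in enumerate(ylev):
        for j, z in enumerate(zs):
            for i, x in enumerate(xs):
                nodes[nid(i, j, k)] = (x, y, z)

    elems = []
    # slab k (bottom to top) belongs to layer layer_of_slab[k]; layer 1 on top
    layer_of_slab = np.repeat(np.arange(n_layers, 0, -1), nz_per_layer)
    layer = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                # ordered for positive Jacobian with y as the "up" axis
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i, j + 1, k),
                        nid(i + 1, j + 1, k),
                        nid(i + 1, j, k),
                        nid(i, j, k + 1),
                        nid(i, j + 1, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i + 1, j, k + 1),
                    ]
                )
                layer.append(layer_of_slab[k])
    elems = np.asarray(elems, dtype=int)
    layer = np.asarray(layer, dtype=int)

    def eid(i, j, k):
        return (k * ny + j) * nx + i

    articular = [(eid(i, j, nz - 1), 5) for j in range(ny) for i in range(nx)]
    bottom = [(eid(i, j, 0), 4) for j in range(ny) for i in range(nx)]
    lateral_x, lateral_z = [], []
    for k in range(nz):
        for j in range(ny):
            lateral_x.append((eid(0, j, k), 2))
            lateral_x.append((eid(nx - 1, j, k), 3))
        for i in range(nx):
            lateral_z.append((eid(i, 0, k), 0))
            lateral_z.append((eid(i, ny - 1, k), 1))

    tags = {
        "articular": np.asarray(articular, dtype=int),
        "bottom": np.asarray(bottom, dtype=int),
        "lateral": np.asarray(lateral_x + lateral_z, dtype=int),
        "lateral_x": np.asarray(lateral_x, dtype=int),   # faces with +-x normals
        "lateral_z": np.asarray(lateral_z, dtype=int),   # faces with +-z normals
    }
    return Mesh(
        nodes=nodes,
        hex_elements=elems,
        layer_id=layer,
        surface_tags=tags,
        depth_axis=np.array([0.0, -1.0, 0.0]),
        surface_point=np.zeros(3),
        thickness=float(thickness),
    )
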