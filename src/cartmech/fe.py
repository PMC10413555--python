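"""Implicit transient biphasic (u-p) finite elements on hexahedral meshes.

A soils-consolidation-style solver: solid momentum balance with effective
stress from the fibril-reinforced constitutive law, fluid mass balance
with Darcy flux, both discretised with equal-order trilinear (8-node)
interpolation and integrated in time by backward Euler.  Loading comes
from surface tractions / nodal forces and from a frictionless rigid
indenter with penalty contact; the indenter can be displacement-driven or
force-driven (the indentation depth is then found by an outer bracketed
secant iteration around the displacement-driven solve until the total
normal force matches its target).

Formulation (total Lagrangian).  Momentum: div(P) = 0 with
P = J sigma F^{-T} and sigma = sigma_eff - p I.  Mass (incompressible
constituents plus a small fluid-compressibility storage):

    d/dt [ J + n_f0 p / K_f ] = Div( k(J) J C^{-1} Grad p ),

with k the strain-dependent permeability and C = F^T F.  Dirichlet p = 0
on free-draining surfaces; sealed surfaces are the natural condition.
Equal-order u-p elements mirror the C3D8P element; a small physical fluid
bulk modulus term keeps the undrained limit well posed, and an optional
pressure-smoothing post-pass is available against checkerboard modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import MaterialParams, MaterialState, evaluate_stress_batch
from .fibrils import FibrilField
from .mesh import Mesh, gauss_points_3d, hex_shape_functions, hex_shape_gradients

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryCondition",
    "RigidIndenter",
    "TimeSchedule",
    "SolverConfig",
    "StepRecord",
    "SolutionHistory",
    "PoroelasticFE",
    "solve_transient",
    "rotation_about_axis",
]

_I3 = np.eye(3)


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return _I3 + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass
class BoundaryCondition:
    """A named boundary condition on a surface tag.

    kind:
      'displacement' : prescribe nodal displacement ``component`` (0..2,
                       or None for all components) to the value series.
      'traction'     : surface traction ``value * direction`` (Pa, on the
                       reference area) on the tagged faces.
      'force'        : total force ``value * direction`` (N) split equally
                       over the tag's nodes.
      'pressure'     : prescribe pore pressure to the value series
                       (free-draining when 0); with ``exclude_footprint``
                       the articular nodes inside the current indenter
                       footprint are left sealed instead.
      'sealed'       : explicit no-flux marker (natural condition).

    ``values`` is a scalar (constant in time) or an array with one entry
    per schedule step.
    """

    kind: str
    target: str
    values: float | np.ndarray = 0.0
    component: int | None = None
    direction: np.ndarray | None = None
    exclude_footprint: bool = True
    name: str = ""

    def value_at(self, step: int, frac: float, n_steps: int) -> float:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 0:
            return float(v)
        if v.size != n_steps:
            raise ValueError(
                f"boundary condition {self.name or self.kind!r}: {v.size} values "
                f"for a schedule of {n_steps} steps")
        prev = v[step - 1] if step > 0 else 0.0
        return float(prev + frac * (v[step] - prev))


@dataclass
class RigidIndenter:
    """Frictionless rigid indenter above the articular surface.

    The indenter frame is (axis1, axis2, normal) with ``normal`` the unit
    vector pointing from the indenter *into* the tissue.  ``center`` is the
    reference contact point at zero depth/offset (on the articular plane).
    Flat indenters have a rectangular footprint ``half_widths`` in the
    (axis1, axis2) plane; spherical indenters a ``radius``.  Control mode
    'force' solves for the depth that matches a target total normal force;
    'displacement' prescribes the depth directly.
    """

    center: np.ndarray
    normal: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray
    shape: str = "flat"
    half_widths: tuple[float, float] = (5e-3, 5e-3)
    radius: float = 5e-3
    control: str = "force"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float) / np.linalg.norm(self.normal)
        self.axis1 = np.asarray(self.axis1, dtype=float) / np.linalg.norm(self.axis1)
        self.axis2 = np.asarray(self.axis2, dtype=float) / np.linalg.norm(self.axis2)
        if self.shape not in ("flat", "sphere"):
            raise ValueError(f"unknown indenter shape {self.shape!r}")
        if self.control not in ("force", "displacement"):
            raise ValueError(f"unknown indenter control {self.control!r}")

    def pose(self, offset1: float, offset2: float, tilt: float):
        """(anchor point q0 at zero depth, tilted frame (a1, a2, n))."""
        R = rotation_about_axis(self.axis1, tilt) if tilt else _I3
        n = R @ self.normal
        a2 = R @ self.axis2
        q0 = self.center + offset1 * self.axis1 + offset2 * self.axis2
        return q0, self.axis1, a2, n


@dataclass
class TimeSchedule:
    """Time-discretised loading program.

    ``times`` are the target solution times (strictly increasing, all
    positive; the initial state sits at t = 0).  Optional per-step indenter
    arrays: target normal force (N) for force control, prescribed depth (m)
    for displacement control, in-plane footprint offsets (m) in the
    indenter frame, and tilt angle (rad).
    """

    times: np.ndarray
    indenter_force: np.ndarray | None = None
    indenter_depth: np.ndarray | None = None
    indenter_offset: np.ndarray | None = None
    indenter_tilt: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("schedule needs at least one time point")
        if self.times[0] <= 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("schedule times must be strictly increasing and positive")
        for name in ("indenter_force", "indenter_depth", "indenter_tilt"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} must match the schedule length")
        if self.indenter_offset is not None:
            self.indenter_offset = np.asarray(self.indenter_offset, dtype=float)
            if self.indenter_offset.shape != (self.times.size, 2):
                raise ValueError("indenter_offset must have shape (n_steps, 2)")

    @property
    def n_steps(self) -> int:
        return self.times.size

    def _interp(self, arr, step, frac, default=0.0):
        if arr is None:
            return default
        prev = arr[step - 1] if step > 0 else np.zeros_like(np.asarray(arr[0]))
        return prev + frac * (arr[step] - prev)


@dataclass
class SolverConfig:
    """Newton/time-stepping controls.

    ``rtol`` is relative to the first residual of each step; absolute
    floors are scaled to the external load (momentum) and mesh volume
    (mass).  ``penalty`` is the contact penalty stiffness in Pa/m.
    """

    rtol: float = 1e-6
    rtol_p: float = 1e-5              # mass-balance relative tolerance
    atol_force: float = 1e-9          # N, absolute momentum floor
    atol_volume_factor: float = 1e-11  # x mesh volume, absolute mass floor (m^3)
    max_iter: int = 80
    max_outer: int = 15               # force-control outer (depth) iterations
    penalty: float = 1e12
    force_tol: float = 0.005          # relative target-force tolerance
    stall_accept: float = 50.0        # accept stalled iterates below this x tolerance
    max_halvings: int = 8
    pressure_smoothing: bool = False
    stab_beta: float = 0.25           # equal-order pressure stabilisation coefficient
    step_cap: float = 0.4             # Newton step cap, fraction of min element edge
    contact_reg: float = 1e-8         # m, C1 regularisation depth of the penalty law
    contact_edge_band: float = 5e-4   # m, C1 taper band at the flat-footprint edge

    def __post_init__(self):
        if self.rtol <= 0 or self.max_iter <= 0 or self.penalty <= 0:
            raise ValueError("tolerances, iteration limits and penalty must be positive")


@dataclass
class StepRecord:
    """Converged solution snapshot at one schedule time."""

    time: float
    u: np.ndarray                     # (N, 3) nodal displacements
    p: np.ndarray                     # (N,) nodal pore pressures
    F_centroid: np.ndarray            # (E, 3, 3) deformation gradient at centroids
    contact_nodes: np.ndarray         # node ids carrying contact force
    contact_forces: np.ndarray        # (n_c, 3) nodal contact force vectors
    total_contact_force: float        # N, along the indenter normal
    indenter_depth: float
    indenter_pose: tuple | None
    reactions: np.ndarray             # (N, 3) reaction forces at prescribed dofs
    drain_reaction: float             # m^3, discrete outflow through drained nodes
    newton_iters: int


@dataclass
class SolutionHistory:
    mesh: Mesh
    records: list[StepRecord] = field(default_factory=list)
    state: MaterialState | None = None
    convergence_log: list[dict] = field(default_factory=list)
    indenter: "RigidIndenter | None" = None

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])


class _NoConvergence(RuntimeError):
    pass


class _Factorized:
    """LU factorisation of an equilibrated sparse system.

    The monolithic u-p system mixes stiffness (N/m), permeability
    (m^3/Pa) and contact-penalty rows whose diagonals differ by many
    orders of magnitude; symmetric Jacobi equilibration keeps the LU from
    polluting the weakly-scaled pressure block, and one pass of iterative
    refinement recovers the absolute accuracy the scaling trades away.
    """

    def __init__(self, K: sp.spmatrix):
        self.K = K.tocsr()
        dg = np.abs(self.K.diagonal())
        dg[dg == 0.0] = 1.0
        self.s = 1.0 / np.sqrt(dg)
        D = sp.diags(self.s)
        self.lu = spla.splu((D @ self.K @ D).tocsc())

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        x = self.s * self.lu.solve(self.s * rhs)
        x += self.s * self.lu.solve(self.s * (rhs - self.K @ x))
        return x


def _scaled_solve(K: sp.spmatrix, rhs: np.ndarray) -> np.ndarray:
    return _Factorized(K).solve(rhs)


class PoroelasticFE:
    """Assembler/solver bound to one mesh + fibril field + material."""

    def __init__(
        self,
        mesh: Mesh,
        fibrils: FibrilField,
        params: MaterialParams,
        bcs: list[BoundaryCondition],
        indenter: RigidIndenter | None = None,
        config: SolverConfig | None = None,
    ):
        self.mesh = mesh
        self.params = params
        self.bcs = bcs
        self.indenter = indenter
        self.config = config or SolverConfig()

        E = mesh.n_elements
        if fibrils.points.shape[0] != 8 * E:
            raise ValueError("fibril field must be built on the mesh's 2x2x2 Gauss points")
        self.fibrils = fibrils

        self._validate_bcs()

        pts, w = gauss_points_3d()
        dN = hex_shape_gradients(pts)          # (8gp, 8, 3)
        self.Nv = hex_shape_functions(pts)     # (8gp, 8)
        xe = mesh.nodes[mesh.hex_elements]
        J0 = np.einsum("gak,eai->egik", dN, xe)
        detJ0 = np.linalg.det(J0)
        J0inv = np.linalg.inv(J0)
        self.G = np.einsum("gak,egki->egai", dN, J0inv)   # (E, 8gp, 8, 3)
        self.wdet = w[None, :] * detJ0                    # (E, 8gp)

        self.conn = mesh.hex_elements
        self.n_nodes = mesh.n_nodes
        self.ndof = 4 * self.n_nodes
        edofs = 4 * self.conn[:, :, None] + np.arange(4)[None, None, :]
        self.edofs = edofs.reshape(E, 32)
        self.Krows = np.repeat(self.edofs[:, :, None], 32, axis=2).ravel()
        self.Kcols = np.repeat(self.edofs[:, None, :], 32, axis=1).ravel()

        self.total_volume = float(mesh.element_volume.sum())

        # polynomial-pressure-projection stabilisation coefficient for the
        # equal-order pair (penalty on intra-element pressure fluctuation)
        nf = params.nonfibrillar
        self.c_stab = self.config.stab_beta / (nf.lambda_m + 2.0 * nf.G_m)

        edges = mesh.nodes[self.conn[:, [0, 1, 2, 3, 0, 1, 2, 3, 4, 5, 6, 7]]] \
            - mesh.nodes[self.conn[:, [1, 2, 3, 0, 4, 5, 6, 7, 5, 6, 7, 4]]]
        self.min_edge = float(np.linalg.norm(edges, axis=2).min())

        if indenter is not None:
            self.surf_nodes, self.surf_areas = mesh.nodal_areas("articular")
            if indenter.shape == "flat":
                self.half_w1, self.half_w2 = indenter.half_widths
        else:
            self.surf_nodes = np.zeros(0, dtype=int)
            self.surf_areas = np.zeros(0)

        # prescribed-pressure node sets (static part)
        self._fd_eps_u = 1e-9
        self._fd_eps_p = 1e-1

    # ---------------- boundary conditions ----------------

    def _validate_bcs(self) -> None:
        disp_targets: dict[tuple, str] = {}
        for bc in self.bcs:
            if bc.kind not in ("displacement", "traction", "force", "pressure", "sealed"):
                raise ValueError(f"unknown boundary condition kind {bc.kind!r}")
            if bc.target not in self.mesh.surface_tags:
                raise ValueError(f"boundary condition targets unknown tag {bc.target!r}")
        # a node may not carry both a prescribed displacement and a nodal
        # force on the same component; sealed and pressure may not coexist
        force_nodes: dict[int, set] = {}
        disp_nodes: dict[int, set] = {}
        sealed_tags = {bc.target for bc in self.bcs if bc.kind == "sealed"}
        for bc in self.bcs:
            nodes = self.mesh.node_set(bc.target)
            comps = range(3) if bc.component is None else [bc.component]
            if bc.kind == "displacement":
                for n in nodes:
                    disp_nodes.setdefault(n, set()).update(comps)
            elif bc.kind == "force":
                for n in nodes:
                    force_nodes.setdefault(n, set()).update(comps)
            if bc.kind == "pressure" and bc.target in sealed_tags:
                raise ValueError(
                    f"tag {bc.target!r} carries both 'sealed' and 'pressure' conditions")
        for n, comps in force_nodes.items():
            if disp_nodes.get(n, set()) & comps:
                raise ValueError(
                    f"node {n} carries both prescribed displacement and force on one component")

    def _dirichlet(self, step: int, frac: float, n_steps: int, footprint_mask=None):
        """(dof indices, values) of prescribed displacement/pressure dofs."""
        idx, val = [], []
        for bc in self.bcs:
            if bc.kind == "displacement":
                nodes = self.mesh.node_set(bc.target)
                v = bc.value_at(step, frac, n_steps)
                comps = range(3) if bc.component is None else [bc.component]
                for c in comps:
                    idx.append(4 * nodes + c)
                    val.append(np.full(nodes.size, v))
            elif bc.kind == "pressure":
                nodes = self.mesh.node_set(bc.target)
                if (bc.exclude_footprint and footprint_mask is not None
                        and bc.target == "articular"):
                    keep = ~footprint_mask[nodes]
                    nodes = nodes[keep]
                v = bc.value_at(step, frac, n_steps)
                idx.append(4 * nodes + 3)
                val.append(np.full(nodes.size, v))
        if idx:
            idx = np.concatenate(idx)
            val = np.concatenate(val)
            # duplicates (e.g. edge nodes shared by tags): later entries win
            order = np.argsort(idx, kind="stable")
            last = {}
            for i in order:
                last[idx[i]] = val[i]
            keys = np.fromiter(last.keys(), dtype=int)
            vals = np.fromiter(last.values(), dtype=float)
            return keys, vals
        return np.zeros(0, dtype=int), np.zeros(0)

    def _external_forces(self, step: int, frac: float, n_steps: int) -> np.ndarray:
        f = np.zeros(self.ndof)
        for bc in self.bcs:
            if bc.kind == "traction":
                v = bc.value_at(step, frac, n_steps)
                if v == 0.0:
                    continue
                d = np.asarray(bc.direction, dtype=float)
                fn = self.mesh.face_node_indices(bc.target)
                areas, _, _ = self.mesh.face_areas_normals(bc.target)
                load = v * (areas / 4.0)[:, None, None] * d[None, None, :]  # (F,1,3)
                load = np.broadcast_to(load, (fn.shape[0], 4, 3))
                for c in range(3):
                    np.add.at(f, 4 * fn.ravel() + c, load[:, :, c].ravel())
            elif bc.kind == "force":
                v = bc.value_at(step, frac, n_steps)
                if v == 0.0:
                    continue
                d = np.asarray(bc.direction, dtype=float)
                nodes = self.mesh.node_set(bc.target)
                for c in range(3):
                    f[4 * nodes + c] += v * d[c] / nodes.size
        return f

    # ---------------- element residual ----------------

    def _element_residual(self, ue, pe, state: MaterialState, Jn, pn_g, pe_n, dt):
        """Element residual vectors (E, 32) for gathered dofs ue (E,8,3), pe (E,8)."""
        E = ue.shape[0]
        gradu = np.einsum("egai,eaj->egji", self.G, ue)      # du_j/dX_i
        F = gradu + _I3
        Fp = F.reshape(-1, 3, 3)
        pg = np.einsum("ga,ea->eg", self.Nv, pe).reshape(-1)
        gradp = np.einsum("egai,ea->egi", self.G, pe).reshape(-1, 3)

        sig_tot, _, _, trial = evaluate_stress_batch(
            Fp, pg, self.fibrils.directions, self.fibrils.weights,
            state, dt, self.params)

        J = np.linalg.det(Fp)
        Finv = np.linalg.inv(Fp)
        P = J[:, None, None] * np.einsum("pjk,pik->pji", sig_tot, Finv)
        P = P.reshape(E, 8, 3, 3)
        r_u = np.einsum("eg,egai,egji->eaj", self.wdet, self.G, P)

        por = self.params.porous
        nf0 = self.fibrils.fluid_fraction
        phi = (J - 1.0 + nf0) / nf0
        if np.any(phi <= 0.0):
            raise FloatingPointError("permeability: compaction limit reached")
        k = por.k_0 * phi ** por.M
        Cinv = np.einsum("pij,pkj->pik", Finv, Finv)         # (F^T F)^{-1}
        q = (k * J)[:, None] * np.einsum("pij,pj->pi", Cinv, gradp)
        storage = (J - Jn) + nf0 * (pg - pn_g) / self.params.fluid_bulk
        r_p = np.einsum("eg,ga,eg->ea", self.wdet, self.Nv, storage.reshape(E, 8)) \
            + dt * np.einsum("eg,egai,egi->ea", self.wdet, self.G, q.reshape(E, 8, 3))
        if self.config.stab_beta > 0.0:
            # local pressure-projection stabilisation (Dohrmann-Bochev type):
            # penalises only the intra-element pressure fluctuation p - Pi p,
            # damping equal-order checkerboard modes without introducing any
            # long-range artificial drainage
            pg_e = pg.reshape(E, 8)
            Ve = self.wdet.sum(axis=1)
            pbar = (self.wdet * pg_e).sum(axis=1) / Ve
            pdev = pg_e - pbar[:, None]
            Ndev = self.Nv[None, :, :] - (np.einsum(
                "eg,ga->ea", self.wdet, self.Nv) / Ve[:, None])[:, None, :]
            r_p += self.c_stab * np.einsum("eg,ega,eg->ea", self.wdet, Ndev, pdev)

        r = np.empty((E, 8, 4))
        r[..., :3] = r_u
        r[..., 3] = r_p
        return r.reshape(E, 32), trial

    # ---------------- contact ----------------

    def _contact(self, u, d, pose):
        """Nodal contact forces and linearisation data.

        The penalty law is C1-regularised: force magnitude per unit area is
        kappa * g(pen) with g quadratic on (0, delta] and linear beyond, so
        Newton sees a smooth residual across contact activation.

        Returns (forces (n_surf, 3), pen, active mask, normal dirs, slope)
        where ``slope`` is d|f|/d pen per node.
        """
        q0, a1, a2, n = pose
        x = self.mesh.nodes[self.surf_nodes] + u[self.surf_nodes]
        kappa = self.config.penalty
        grad_wt = np.zeros_like(x)
        if self.indenter.shape == "flat":
            w = x - (q0 + d * n)
            pen = -(w @ n)
            band = self.config.contact_edge_band

            def edge_w(dist_in):
                # rounded punch edge: C1 taper over `band`, with derivative
                if band <= 0:
                    return (dist_in >= 0).astype(float), np.zeros_like(dist_in)
                t = np.clip(dist_in / band, 0.0, 1.0)
                return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t) / band

            s1 = self.half_w1 - np.abs(w @ a1)
            s2 = self.half_w2 - np.abs(w @ a2)
            W1, dW1 = edge_w(s1)
            W2, dW2 = edge_w(s2)
            wt = W1 * W2
            # d wt / d u = W1' W2 ds1/du + W1 W2' ds2/du, ds/du = -sign(w.a) a
            grad_wt = (-(dW1 * W2) * np.sign(w @ a1))[:, None] * a1 \
                + (-(W1 * dW2) * np.sign(w @ a2))[:, None] * a2
            active = (wt > 0.0) & (pen > 0.0)
            dirs = np.broadcast_to(n, x.shape)
        else:
            cs = q0 + d * n - self.indenter.radius * n   # sphere centre
            rel = x - cs
            dist = np.linalg.norm(rel, axis=1)
            pen = self.indenter.radius - dist
            active = pen > 0.0
            dirs = rel / np.maximum(dist, 1e-30)[:, None]
            wt = np.ones_like(pen)
        pen = np.where(active, pen, 0.0)
        delta = self.config.contact_reg
        if delta > 0.0:
            g = np.where(pen <= delta, 0.5 * pen * pen / delta, pen - 0.5 * delta)
            slope = kappa * self.surf_areas * wt * np.where(
                pen <= delta, pen / delta, 1.0) * active
        else:
            g = pen
            slope = kappa * self.surf_areas * wt * active
        forces = kappa * (self.surf_areas * wt * g)[:, None] * dirs
        # in-plane stiffness from the taper: d|f|/du = kappa a g grad_wt
        taper_grad = (kappa * self.surf_areas * g * active)[:, None] * grad_wt
        return forces, pen, active, dirs, slope, taper_grad

    def _touchdown_depth(self, u, pose):
        q0, a1, a2, n = pose
        x = self.mesh.nodes[self.surf_nodes] + u[self.surf_nodes]
        w = x - q0
        if self.indenter.shape == "flat":
            inside = (np.abs(w @ a1) <= self.half_w1) & (np.abs(w @ a2) <= self.half_w2)
            if not np.any(inside):
                return 0.0
            return float(np.min((w @ n)[inside]))
        # sphere: depth at which the surface first reaches each node,
        # accounting for the curvature sag at its lateral offset
        R = self.indenter.radius
        wn = w @ n
        lat2 = np.einsum("ij,ij->i", w, w) - wn**2
        reach = lat2 < R * R
        if not np.any(reach):
            return 0.0
        touch = wn[reach] + R - np.sqrt(R * R - lat2[reach])
        return float(np.min(touch))

    # ---------------- solve ----------------

    def solve(self, schedule: TimeSchedule) -> SolutionHistory:
        cfg = self.config
        mesh = self.mesh
        E = mesh.n_elements
        D = self.fibrils.n_directions
        state = MaterialState.initial(8 * E, D)
        u = np.zeros((self.n_nodes, 3))
        p = np.zeros(self.n_nodes)
        d = 0.0

        history = SolutionHistory(mesh=mesh, indenter=self.indenter)
        t_prev = 0.0
        n_steps = schedule.n_steps
        for step in range(n_steps):
            t_target = schedule.times[step]
            frac_done = 0.0
            halvings = 0
            frac_step = 1.0
            while frac_done < 1.0 - 1e-12:
                frac = min(1.0, frac_done + frac_step)
                dt = (t_target - t_prev) * (frac - frac_done)
                try:
                    u_new, p_new, d_new, trial, info = self._solve_increment(
                        u, p, d, state, dt, step, frac, n_steps, schedule)
                except (_NoConvergence, FloatingPointError) as err:
                    halvings += 1
                    if halvings > cfg.max_halvings:
                        raise RuntimeError(
                            f"step {step}: no convergence at minimal time increment "
                            f"(worst residual: {err})") from err
                    frac_step *= 0.5
                    logger.info("step %d: halving increment to %g", step, frac_step)
                    continue
                frac_step = min(1.5 * frac_step, 1.0)  # regrow after success
                u, p, d = u_new, p_new, d_new
                state.sigma_M, state.eps_prev = trial
                gradu = np.einsum("egai,eaj->egji", self.G, u[self.conn])
                state.F = (gradu + _I3).reshape(-1, 3, 3)
                state.p = np.einsum("ga,ea->eg", self.Nv, p[self.conn]).reshape(-1)
                frac_done = frac
            t_prev = t_target

            p_out = (self._smooth_pressure(p, info["pres_p_idx"])
                     if cfg.pressure_smoothing else p)
            history.records.append(self._record(t_target, u, p_out, d, info))
            history.convergence_log.append(
                {"step": step, "iters": info["iters"], "halvings": halvings})
        history.state = state
        return history

    def _solve_increment(self, u0, p0, d0, state, dt, step, frac, n_steps, schedule):
        cfg = self.config

        # indenter pose & control at this (sub)step
        pose = None
        force_target = None
        d = d0
        if self.indenter is not None:
            off = schedule._interp(schedule.indenter_offset, step, frac,
                                   default=np.zeros(2))
            tilt = float(schedule._interp(schedule.indenter_tilt, step, frac))
            pose = self.indenter.pose(off[0], off[1], tilt)
            if self.indenter.control == "force":
                if schedule.indenter_force is None:
                    raise ValueError("force-driven indenter needs schedule.indenter_force")
                force_target = float(schedule._interp(schedule.indenter_force, step, frac))
            else:
                if schedule.indenter_depth is None:
                    raise ValueError("displacement-driven indenter needs schedule.indenter_depth")
                d = float(schedule._interp(schedule.indenter_depth, step, frac))

        # drainage: articular nodes inside the footprint are sealed
        footprint_mask = None
        if pose is not None:
            footprint_mask = np.zeros(self.n_nodes, dtype=bool)
            q0, a1, a2, n = pose
            x = self.mesh.nodes[self.surf_nodes] + u0[self.surf_nodes]
            w = x - q0
            if self.indenter.shape == "flat":
                ins = (np.abs(w @ a1) <= self.half_w1) & (np.abs(w @ a2) <= self.half_w2)
            else:
                # seal only the current contact patch of the sphere
                dd = max(d, 0.0)
                a_patch = np.sqrt(max(2.0 * self.indenter.radius * dd - dd * dd, 0.0))
                lat = w - np.outer(w @ n, n)
                ins = np.linalg.norm(lat, axis=1) <= a_patch
            footprint_mask[self.surf_nodes[ins]] = True

        pres_idx, pres_val = self._dirichlet(step, frac, n_steps, footprint_mask)
        f_ext = self._external_forces(step, frac, n_steps)

        dofvec = np.empty(self.ndof)
        dofvec[0::4], dofvec[1::4], dofvec[2::4] = u0[:, 0], u0[:, 1], u0[:, 2]
        dofvec[3::4] = p0
        dofvec[pres_idx] = pres_val
        free = np.ones(self.ndof, dtype=bool)
        free[pres_idx] = False

        ctx = {
            "state": state, "dt": dt, "pose": pose, "f_ext": f_ext,
            "free": free, "Jn": np.linalg.det(state.F), "pn_g": state.p,
            "pe_n": p0[self.conn],
            "load_scale": max(np.abs(f_ext).max() if f_ext.size else 0.0,
                              (force_target or 0.0)),
        }

        total_iters = 0
        if force_target is None or force_target <= 0.0:
            if pose is not None and force_target is not None:
                d = self._touchdown_depth(u0, pose)   # rest at touch-down
            dofvec, r, trial, cinfo, iters = self._newton_fixed_depth(dofvec, d, ctx)
            total_iters = iters
        else:
            # force control: outer secant iteration on the indentation depth
            # around the displacement-driven inner solver
            touch = self._touchdown_depth(u0, pose)
            d = max(d0, touch + 1e-9)
            # 0.5% of the target, with an absolute floor for the near-zero
            # tails of the stance (0.5% of 10% of the schedule peak)
            peak_force = float(np.nanmax(schedule.indenter_force))
            tol_N = max(cfg.force_tol * max(force_target, 0.1 * peak_force),
                        cfg.atol_force)
            d_hist, N_hist = [], []
            best = None
            for outer in range(cfg.max_outer):
                # loose inner solves while homing in on the depth; a tight
                # pass seals the step once the force target is met
                dofvec, r, trial, cinfo, iters = self._newton_fixed_depth(
                    dofvec, d, ctx, tol_scale=30.0)
                total_iters += iters
                N = cinfo[4]
                if abs(N - force_target) <= tol_N:
                    dofvec, r, trial, cinfo, iters = self._newton_fixed_depth(
                        dofvec, d, ctx)
                    total_iters += iters
                    N = cinfo[4]
                if logger.isEnabledFor(logging.DEBUG):
                    logger.debug("  outer %d: d=%.5g N=%.4f target=%.4f (%d inner)",
                                 outer, d, N, force_target, iters)
                if best is None or abs(N - force_target) < abs(best[2] - force_target):
                    best = (dofvec.copy(), d, N, r.copy(), trial, cinfo)
                if abs(N - force_target) <= tol_N:
                    break
                d_hist.append(d)
                N_hist.append(N)
                # maintain a bracket around the target where available
                lo = [(dd, NN) for dd, NN in zip(d_hist, N_hist) if NN < force_target]
                hi = [(dd, NN) for dd, NN in zip(d_hist, N_hist) if NN > force_target]
                if lo and hi:
                    d_lo, N_lo = max(lo)
                    d_hi, N_hi = min(hi)
                    # false position inside the bracket (N is monotone in d)
                    d_new = d_lo + (force_target - N_lo) * (d_hi - d_lo) \
                        / max(N_hi - N_lo, 1e-30)
                    d = float(np.clip(d_new, d_lo + 0.05 * (d_hi - d_lo),
                                      d_hi - 0.05 * (d_hi - d_lo)))
                    continue
                # no bracket yet: secant if descent-consistent, else a stiff
                # (undrained) first estimate; undershooting is cheap, the
                # overshot inner solve is not
                dN_dd = None
                if len(d_hist) >= 2 and abs(d_hist[-1] - d_hist[-2]) > 1e-15:
                    slope_sec = (N_hist[-1] - N_hist[-2]) / (d_hist[-1] - d_hist[-2])
                    if slope_sec > 0:
                        dN_dd = slope_sec
                if dN_dd is None:
                    dN_dd = self._undrained_contact_stiffness()
                step_d = (force_target - N) / max(dN_dd, 1e-30)
                cap = 0.02 * self.mesh.thickness if len(d_hist) < 2 \
                    else 4.0 * abs(d_hist[-1] - d_hist[-2]) + 1e-9
                cap = min(cap, 0.2 * self.mesh.thickness)
                step_d = float(np.clip(step_d, -cap, cap))
                if N <= 0 and step_d <= 0:
                    step_d = max(touch + 1e-9 - d, 1e-7)
                d = d + step_d
            else:
                dofvec, d, N, r, trial, cinfo = best
                if abs(N - force_target) > 5 * tol_N:
                    raise _NoConvergence(
                        f"force control: |N - target| = {abs(N - force_target):.3g} N")
            if abs(cinfo[4] - force_target) > tol_N:
                dofvec, d, N, r, trial, cinfo = best
                if abs(N - force_target) > tol_N:
                    raise _NoConvergence(
                        f"force control: |N - target| = {abs(N - force_target):.3g} N")

        u = np.stack([dofvec[0::4], dofvec[1::4], dofvec[2::4]], axis=1)
        p = dofvec[3::4]
        reactions = np.zeros((self.n_nodes, 3))
        drain = 0.0
        pres_p = pres_idx[pres_idx % 4 == 3]
        if pres_idx.size:
            ru_idx = pres_idx[pres_idx % 4 != 3]
            reactions[(ru_idx // 4), (ru_idx % 4)] = r[ru_idx]
            drain = float(r[pres_p].sum())
        info = {
            "iters": total_iters,
            "contact": cinfo,
            "pose": pose,
            "reactions": reactions,
            "drain": drain,
            "pres_p_idx": pres_p,
        }
        return u, p, d, trial, info

    def _undrained_contact_stiffness(self) -> float:
        """Stiff first estimate of dN/d(depth): undrained instantaneous
        tissue column under the footprint (matrix plus taut fibrils)."""
        nf = self.params.nonfibrillar
        fb = self.params.fibril
        if self.indenter is not None and self.indenter.shape == "flat":
            area = 4.0 * self.half_w1 * self.half_w2
        else:
            area = float(self.surf_areas.sum())
        w_mean = float(self.fibrils.weights.sum(axis=1).mean())
        E_inst = nf.lambda_m + 2.0 * nf.G_m + w_mean * (fb.E_0 + fb.E_eps)
        return E_inst * area / max(self.mesh.thickness, 1e-9)

    def _full_residual(self, dofvec, d, ctx):
        """Assembled residual at fixed indenter depth; returns (r, trial, cinfo)."""
        ue = np.stack([dofvec[0::4], dofvec[1::4], dofvec[2::4]], axis=1)[self.conn]
        pe = dofvec[3::4][self.conn]
        r_e, trial = self._element_residual(ue, pe, ctx["state"], ctx["Jn"],
                                            ctx["pn_g"], ctx["pe_n"], ctx["dt"])
        r = np.zeros(self.ndof)
        np.add.at(r, self.edofs.ravel(), r_e.ravel())
        r -= ctx["f_ext"]
        cinfo = None
        if ctx["pose"] is not None:
            forces, pen, active, dirs, _, _ = self._contact(
                np.stack([dofvec[0::4], dofvec[1::4], dofvec[2::4]], axis=1),
                d, ctx["pose"])
            for c in range(3):
                np.add.at(r, 4 * self.surf_nodes + c, -forces[:, c])
            N_total = float((forces @ ctx["pose"][3]).sum())
            cinfo = (forces, pen, active, dirs, N_total)
        return r, trial, cinfo

    def _newton_fixed_depth(self, dofvec, d, ctx, tol_scale: float = 1.0):
        """Damped Newton at fixed boundary data and indenter depth.

        The Jacobian is cached across iterations (and across outer
        force-control iterations via ``ctx``): it is rebuilt only when the
        cached one contracts the residual poorly.  ``tol_scale`` loosens
        the convergence measure for intermediate outer iterations.
        """
        cfg = self.config
        free = ctx["free"]
        dofvec = dofvec.copy()
        atol_p = cfg.atol_volume_factor * self.total_volume
        load_scale = ctx["load_scale"]
        umask_full = np.arange(self.ndof) % 4 != 3
        umask = umask_full[free]
        fidx = np.flatnonzero(free)
        r0_u = None
        ref_p = atol_p
        ru_hist: list[float] = []
        iters = 0
        prev_measure = None
        for it in range(cfg.max_iter):
            r, trial, cinfo = self._full_residual(dofvec, d, ctx)
            rf = r[free]
            ru = np.abs(rf[umask]).max() if np.any(umask) else 0.0
            rp = np.abs(rf[~umask]).max() if np.any(~umask) else 0.0
            if r0_u is None:
                r0_u = ru
            ref_p = max(ref_p, rp)
            tol_u = max(cfg.rtol * max(load_scale, r0_u), cfg.atol_force)
            tol_p = max(cfg.rtol_p * ref_p, atol_p)
            measure = max(ru / tol_u, rp / tol_p)
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug("    it=%d ru=%.3e rp=%.3e N=%.4g d=%.4g",
                             it, ru, rp, cinfo[4] if cinfo else 0.0, d)
            if measure <= tol_scale:
                return dofvec, r, trial, cinfo, it
            # stall / iteration-budget handling: an iterate within
            # ``stall_accept`` times the tolerance (i.e. still a tiny
            # fraction of the load scale) is accepted rather than failed
            if it == cfg.max_iter - 1:
                if measure <= cfg.stall_accept:
                    logger.info("accepting near-converged iterate (measure %.3g)",
                                measure)
                    return dofvec, r, trial, cinfo, it
                raise _NoConvergence(f"|r_u|={ru:.3e} |r_p|={rp:.3e}")
            ru_hist.append(measure)
            best = min(ru_hist)
            since_best = len(ru_hist) - 1 - max(
                i for i, v in enumerate(ru_hist) if v <= 1.05 * best)
            if len(ru_hist) >= 20 and since_best >= 12:
                if measure <= cfg.stall_accept:
                    logger.info("accepting stalled iterate (measure %.3g)", measure)
                    return dofvec, r, trial, cinfo, it
                raise _NoConvergence(
                    f"stalled (best scaled residual {best:.3e}, current {measure:.3e})")

            # modified Newton: rebuild the tangent only when the cached one
            # stops contracting the residual, and at most every few iterations
            # (in the damped-walk phase a fresh tangent buys little)
            stale = prev_measure is not None and measure > 0.3 * prev_measure
            if ctx.get("fact") is None or stale:
                K = self._jacobian(dofvec, d, ctx["state"], ctx["Jn"], ctx["pn_g"],
                                   ctx["pe_n"], ctx["dt"], ctx["pose"], False, 1.0)
                ctx["fact"] = _Factorized(K[fidx][:, fidx])
            prev_measure = measure
            du_step = ctx["fact"].solve(-rf)

            # step cap + backtracking on the momentum residual: the tension-only
            # fibrils stiffen strongly, so raw Newton from a slack state overshoots
            du_max = np.abs(du_step[umask]).max() if du_step.size else 0.0
            alpha = min(1.0, cfg.step_cap * self.min_edge / max(du_max, 1e-30))
            n_back = 0
            while True:
                dof_try = dofvec.copy()
                dof_try[free] += alpha * du_step
                try:
                    r_t, _, _ = self._full_residual(dof_try, d, ctx)
                except FloatingPointError:
                    alpha *= 0.5
                    n_back += 1
                    if n_back > 10:
                        raise _NoConvergence("line search failed (element inversion)")
                    continue
                rut = np.abs(r_t[free][umask]).max() if np.any(umask) else 0.0
                # accept any step that keeps momentum within tolerance: the
                # remaining (quasi-linear) mass correction needs full steps
                if rut <= max(ru, tol_u) or alpha <= 1.0 / 64.0:
                    break
                alpha *= 0.5
                n_back += 1
            dofvec = dof_try
            iters = it + 1
        return dofvec, r, trial, cinfo, iters

    def _jacobian(self, dofvec, d, state, Jn, pn_g, pe_n, dt, pose, force_driven, scale_C):
        E = self.mesh.n_elements
        ue = np.stack([dofvec[0::4], dofvec[1::4], dofvec[2::4]], axis=1)[self.conn]
        pe = dofvec[3::4][self.conn]
        # central differences: at the tension-only fibril kink this yields the
        # semismooth average of the slack/taut branch stiffnesses
        Ke = np.empty((E, 32, 32))
        for k in range(32):
            a, c = divmod(k, 4)
            if c < 3:
                eps = self._fd_eps_u
                ue_p = ue.copy()
                ue_p[:, a, c] += eps
                r1, _ = self._element_residual(ue_p, pe, state, Jn, pn_g, pe_n, dt)
                ue_p[:, a, c] -= 2 * eps
                r2, _ = self._element_residual(ue_p, pe, state, Jn, pn_g, pe_n, dt)
            else:
                eps = self._fd_eps_p
                pe_p = pe.copy()
                pe_p[:, a] += eps
                r1, _ = self._element_residual(ue, pe_p, state, Jn, pn_g, pe_n, dt)
                pe_p[:, a] -= 2 * eps
                r2, _ = self._element_residual(ue, pe_p, state, Jn, pn_g, pe_n, dt)
            Ke[:, :, k] = (r1 - r2) / (2 * eps)

        size = self.ndof + (1 if force_driven else 0)
        rows = [self.Krows]
        cols = [self.Kcols]
        data = [Ke.ravel()]

        if pose is not None:
            u = np.stack([dofvec[0::4], dofvec[1::4], dofvec[2::4]], axis=1)
            forces, pen, active, dirs, slope, taper = self._contact(u, d, pose)
            kappa = self.config.penalty
            act = np.flatnonzero(active)
            if act.size:
                nodes = self.surf_nodes[act]
                nn = dirs[act]
                ka = slope[act]   # regularised stiffness d|f|/d pen per node
                tg = taper[act]   # in-plane taper stiffness d|f|/du
                # d r_u / d u: n (slope n - taper_grad)^T at active nodes
                for ci in range(3):
                    for cj in range(3):
                        rows.append(4 * nodes + ci)
                        cols.append(4 * nodes + cj)
                        data.append(nn[:, ci] * (ka * nn[:, cj] - tg[:, cj]))
                if force_driven:
                    nvec = pose[3]
                    # d r_u / d depth = -slope (n . n_t) n ; flat: n == n_t
                    coup = ka * (nn @ nvec)
                    for ci in range(3):
                        rows.append(4 * nodes + ci)
                        cols.append(np.full(act.size, self.ndof))
                        data.append(-coup * nn[:, ci])
                    # d C / d u = (-slope n + taper_grad)^T ; d C / d depth = sum slope
                    for cj in range(3):
                        rows.append(np.full(act.size, self.ndof))
                        cols.append(4 * nodes + cj)
                        data.append(scale_C * (-ka * nn[:, cj] + tg[:, cj]))
                    rows.append(np.array([self.ndof]))
                    cols.append(np.array([self.ndof]))
                    data.append(np.array([scale_C * coup.sum()]))
            elif force_driven:
                # no active nodes: give the depth equation a descent direction
                rows.append(np.array([self.ndof]))
                cols.append(np.array([self.ndof]))
                data.append(np.array([scale_C * kappa * max(self.surf_areas.sum(), 1e-30)]))

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        return sp.csr_matrix((data, (rows, cols)), shape=(size, size))

    def _smooth_pressure(self, p, drained_idx):
        """One Jacobi averaging pass over element neighbourhoods (optional)."""
        acc = np.zeros_like(p)
        cnt = np.zeros_like(p)
        pe_mean = p[self.conn].mean(axis=1)
        np.add.at(acc, self.conn.ravel(), np.repeat(pe_mean, 8))
        np.add.at(cnt, self.conn.ravel(), 1.0)
        ps = acc / np.maximum(cnt, 1.0)
        drained_nodes = drained_idx // 4
        ps[drained_nodes] = p[drained_nodes]
        return ps

    def _record(self, time, u, p, d, info) -> StepRecord:
        gradu = np.einsum("eai,eaj->eji", _centroid_grads(self), u[self.conn])
        Fc = gradu + _I3
        cinfo = info["contact"]
        if cinfo is not None:
            forces, pen, active, dirs, N_total = cinfo
            act = np.flatnonzero(active)
            c_nodes = self.surf_nodes[act]
            c_forces = forces[act]
        else:
            c_nodes = np.zeros(0, dtype=int)
            c_forces = np.zeros((0, 3))
            N_total = 0.0
        return StepRecord(
            time=time, u=u.copy(), p=p.copy(), F_centroid=Fc,
            contact_nodes=c_nodes, contact_forces=c_forces,
            total_contact_force=float(N_total), indenter_depth=float(d),
            indenter_pose=info["pose"], reactions=info["reactions"],
            drain_reaction=info["drain"], newton_iters=info["iters"],
        )


def _centroid_grads(solver: PoroelasticFE) -> np.ndarray:
    """dN/dX at element centroids, (E, 8, 3); cached on the solver."""
    if not hasattr(solver, "_cgrads"):
        dN = hex_shape_gradients(np.zeros(3))         # (8, 3)
        xe = solver.mesh.nodes[solver.conn]
        J0 = np.einsum("ak,eai->eik", dN, xe)
        J0inv = np.linalg.inv(J0)
        solver._cgrads = np.einsum("ak,eki->eai", dN, J0inv)
    return solver._cgrads


def solve_transient(
    mesh: Mesh,
    fibrils: FibrilField,
    params: MaterialParams,
    schedule: TimeSchedule,
    bcs: list[BoundaryCondition],
    indenter: RigidIndenter | None = None,
    config: SolverConfig | None = None,
) -> SolutionHistory:
    """Run the transient consolidation analysis over a loading schedule."""
    solver = PoroelasticFE(mesh, fibrils, params, bcs, indenter, config)
    return solver.solve(schedule)
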