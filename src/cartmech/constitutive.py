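"""Fibril-reinforced poro(visco)elastic material response at a point.

The tissue is biphasic: an incompressible pore fluid in a porous solid.
The effective (solid) stress combines

* a compressible Neo-Hookean ground matrix representing the proteoglycan
  gel, weighted by (1 - total fibril density), and
* a set of tension-only collagen fibrils.  Cartilage fibrils (FRPVE) are
  viscoelastic: a standard-linear-solid with an equilibrium spring E_0 in
  parallel with a Maxwell branch (E_eps, eta), integrated by backward
  Euler.  Meniscal fibrils (FRPE) are the same network with the Maxwell
  branch switched off.

Permeability is strain-dependent, k = k_0 ((J - 1 + n_f0)/n_f0)^M, so the
tissue consolidates more slowly as it compacts.  Total Cauchy stress is
effective stress minus pore pressure: sigma_total = sigma_eff - p I.

Parameter values are literature-informed defaults for healthy articular
cartilage, not measurements; all are config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NonFibrillarParams",
    "FibrilParams",
    "PorousParams",
    "MaterialParams",
    "MaterialState",
    "FibrilDirectionState",
    "StressResult",
    "fibril_strain",
    "neo_hookean_stress",
    "fibril_stress_update",
    "fibril_stress_batch",
    "total_stress",
    "evaluate_stress_batch",
    "permeability",
    "material_preset",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class NonFibrillarParams:
    """Neo-Hookean ground-matrix moduli (Pa)."""

    G_m: float = 0.5e6
    lambda_m: float = 0.1e6

    def __post_init__(self):
        if not self.G_m > 0:
            raise ValueError("G_m must be positive")
        if self.lambda_m < 0:
            raise ValueError("lambda_m must be non-negative")


@dataclass(frozen=True)
class FibrilParams:
    """Tension-only fibril network.

    E_0: equilibrium spring modulus (Pa); E_eps: Maxwell-branch modulus
    (Pa); eta: dashpot viscosity (Pa s).  ``viscoelastic`` toggles
    FRPVE (on) vs FRPE (off).  ``strain_stiffening`` switches the elastic
    spring to the strain-stiffening form E_0 eps + E_eps eps^2 (elastic
    networks only).
    """

    E_0: float = 5.0e6
    E_eps: float = 100.0e6
    eta: float = 1000.0e6
    viscoelastic: bool = True
    strain_stiffening: bool = False

    def __post_init__(self):
        if self.E_0 < 0 or self.E_eps < 0:
            raise ValueError("fibril moduli must be non-negative")
        if self.viscoelastic and not self.eta > 0:
            raise ValueError("eta must be positive for a viscoelastic fibril network")


@dataclass(frozen=True)
class PorousParams:
    """Strain-dependent permeability: k_0 in m^4/(N s), exponent M, reference fluid fraction n_f0."""

    k_0: float = 2.0e-15
    M: float = 5.0
    n_f0: float = 0.8

    def __post_init__(self):
        if not self.k_0 > 0:
            raise ValueError("k_0 must be positive")
        if not (0.0 < self.n_f0 < 1.0):
            raise ValueError("n_f0 must lie in (0, 1)")


@dataclass(frozen=True)
class MaterialParams:
    """Bundle of the three constitutive parameter blocks plus fluid bulk modulus.

    ``fluid_bulk`` (Pa) is the pore-fluid bulk modulus entering the storage
    term of the mass balance; water at 2.2 GPa is effectively incompressible
    at tissue stress levels but keeps the undrained problem well-posed.
    """

    nonfibrillar: NonFibrillarParams = field(default_factory=NonFibrillarParams)
    fibril: FibrilParams = field(default_factory=FibrilParams)
    porous: PorousParams = field(default_factory=PorousParams)
    fluid_bulk: float = 2.2e9


@dataclass
class FibrilDirectionState:
    """Viscoelastic history of a single fibril direction."""

    sigma_M: float = 0.0
    eps_prev: float = 0.0


@dataclass
class MaterialState:
    """Per-point history for a batch of P material points with D fibril directions."""

    sigma_M: np.ndarray    # (P, D) Maxwell-branch stresses (Pa)
    eps_prev: np.ndarray   # (P, D) previous fibril log strains
    F: np.ndarray          # (P, 3, 3) deformation gradients
    p: np.ndarray          # (P,) pore pressures (Pa)

    @classmethod
    def initial(cls, n_points: int, n_directions: int) -> "MaterialState":
        F = np.broadcast_to(_I3, (n_points, 3, 3)).copy()
        return cls(
            sigma_M=np.zeros((n_points, n_directions)),
            eps_prev=np.zeros((n_points, n_directions)),
            F=F,
            p=np.zeros(n_points),
        )

    def copy(self) -> "MaterialState":
        return MaterialState(self.sigma_M.copy(), self.eps_prev.copy(),
                             self.F.copy(), self.p.copy())


@dataclass
class StressResult:
    """Biphasic stress split at a point: total = effective - p I."""

    total: np.ndarray              # (3, 3) Cauchy stress, Pa
    effective: np.ndarray          # (3, 3) effective solid stress, Pa
    fibril_stresses: np.ndarray    # (D,) per-direction fibril stresses, Pa


# -- kinematic / constituent kernels -------------------------------------


def fibril_strain(F: np.ndarray, e_f: np.ndarray) -> float:
    """Logarithmic stretch along a fibril: eps_f = ln |F e_f|."""
    F = np.asarray(F, dtype=float)
    e_f = np.asarray(e_f, dtype=float)
    if abs(np.linalg.norm(e_f) - 1.0) > 1e-8:
        raise ValueError("e_f must be a unit vector")
    if np.linalg.det(F) <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    return float(np.log(np.linalg.norm(F @ e_f)))


def neo_hookean_stress(F: np.ndarray, params: NonFibrillarParams) -> np.ndarray:
    """Compressible Neo-Hookean Cauchy stress.

    sigma = (G/J)(B - I) + (lambda ln J / J) I, B = F F^T, J = det F.
    Reduces to linear isotropic elasticity (G, lambda) at small strain.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("element inversion: det F <= 0")
    B = F @ F.T
    return (params.G_m / J) * (B - _I3) + (params.lambda_m * np.log(J) / J) * _I3


def fibril_stress_update(
    eps_f_now: float,
    state: FibrilDirectionState,
    dt: float,
    params: FibrilParams,
) -> tuple[float, FibrilDirectionState]:
    """Tension-only SLS fibril stress and updated history (backward Euler).

    sigma_M <- (sigma_M + E_eps * d_eps) / (1 + dt E_eps / eta);
    total = max(E_0 eps + sigma_M, 0); the Maxwell state resets whenever
    the fibril is slack (eps <= 0).  With the viscoelastic flag off the
    fibril is a plain tension-only spring and the state is untouched.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    s, snew = _fibril_stress_core(
        np.asarray([eps_f_now]), np.asarray([state.sigma_M]),
        np.asarray([state.eps_prev]), dt, params,
    )
    if not params.viscoelastic:
        return float(s[0]), state
    return float(s[0]), FibrilDirectionState(sigma_M=float(snew[0][0]),
                                             eps_prev=float(snew[1][0]))


def _fibril_stress_core(eps, sigma_M, eps_prev, dt, params: FibrilParams):
    # The stress is evaluated smoothly in eps (only the tension clamp's
    # mild kink remains); the slack reset of the Maxwell history applies to
    # the *returned* state, i.e. it takes effect when a converged step is
    # committed.  An instantaneous in-iteration reset would make the stress
    # discontinuous in strain, which defeats Newton during unloading.
    eps = np.asarray(eps, dtype=float)
    if params.strain_stiffening:
        elastic = params.E_0 * eps + params.E_eps * eps * eps * np.sign(eps)
    else:
        elastic = params.E_0 * eps
    if not params.viscoelastic:
        return np.maximum(elastic, 0.0), (sigma_M, eps_prev)
    d_eps = eps - eps_prev
    sM = (sigma_M + params.E_eps * d_eps) / (1.0 + dt * params.E_eps / params.eta)
    total = np.maximum(elastic + sM, 0.0)
    sM_commit = np.where(eps <= 0.0, 0.0, sM)
    return total, (sM_commit, eps.copy())


def fibril_stress_batch(eps, sigma_M, eps_prev, dt, params: FibrilParams):
    """Vectorised SLS update over arbitrary-shaped strain arrays.

    Returns (stress, new_sigma_M, new_eps_prev); the inputs are untouched.
    """
    s, (sM, ep) = _fibril_stress_core(eps, sigma_M, eps_prev, dt, params)
    if not params.viscoelastic:
        return s, np.asarray(sigma_M).copy(), np.asarray(eps_prev).copy()
    return s, sM, ep


def permeability(J, params: PorousParams):
    """Strain-dependent permeability k(J) = k_0 ((J - 1 + n_f0)/n_f0)^M."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 1.0 - params.n_f0):
        raise ValueError("J at or below the compaction limit 1 - n_f0")
    k = params.k_0 * ((J - 1.0 + params.n_f0) / params.n_f0) ** params.M
    return k if k.ndim else float(k)


# -- composed response ----------------------------------------------------


def evaluate_stress_batch(
    F: np.ndarray,
    p: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray,
    state: MaterialState,
    dt: float,
    params: MaterialParams,
):
    """Total/effective Cauchy stress for a batch of P points.

    Parameters: F (P,3,3), p (P,), directions (P,D,3), weights (P,D);
    ``state`` carries the committed history at the previous converged step.

    Returns (sigma_total (P,3,3), sigma_eff (P,3,3), fibril stresses (P,D),
    trial (sigma_M, eps_prev)).  The trial history must only be committed
    into ``state`` after the global solve converges.
    """
    F = np.asarray(F, dtype=float)
    P = F.shape[0]
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise FloatingPointError("element inversion: det F <= 0 at a material point")
    B = np.einsum("pij,pkj->pik", F, F)
    nf = params.nonfibrillar
    sig_nh = (nf.G_m / J)[:, None, None] * (B - _I3) \
        + (nf.lambda_m * np.log(J) / J)[:, None, None] * _I3

    rho = weights.sum(axis=1)
    Fe = np.einsum("pij,pdj->pdi", F, directions)   # pushed-forward fibrils
    L = np.linalg.norm(Fe, axis=2)
    eps_f = np.log(L)
    e_hat = Fe / L[..., None]

    sig_f, sM, ep = fibril_stress_batch(eps_f, state.sigma_M, state.eps_prev,
                                        dt, params.fibril)
    fib = np.einsum("pd,pdi,pdj->pij", weights * sig_f, e_hat, e_hat)

    sig_eff = (1.0 - rho)[:, None, None] * sig_nh + fib
    sig_tot = sig_eff - np.asarray(p, dtype=float)[:, None, None] * _I3
    return sig_tot, sig_eff, sig_f, (sM, ep)


def total_stress(
    F: np.ndarray,
    p: float,
    directions: np.ndarray,
    weights: np.ndarray,
    state: MaterialState,
    dt: float,
    params: MaterialParams,
) -> tuple[StressResult, tuple[np.ndarray, np.ndarray]]:
    """Single-point convenience wrapper around :func:`evaluate_stress_batch`.

    ``directions`` (D,3), ``weights`` (D,); ``state`` must hold one point.
    Returns the stress split and the trial fibril history.
    """
    tot, eff, sf, trial = evaluate_stress_batch(
        np.asarray(F, dtype=float)[None], np.asarray([p], dtype=float),
        np.asarray(directions, dtype=float)[None],
        np.asarray(weights, dtype=float)[None],
        state, dt, params,
    )
    return StressResult(total=tot[0], effective=eff[0], fibril_stresses=sf[0]), trial


def material_preset(name: str) -> MaterialParams:
    """Named presets: ``cartilage_frpve``, ``meniscus_frpe``, ``bone_linear``.

    ``bone_linear`` maps an isotropic linear-elastic bone (E = 10 GPa,
    nu = 0.3) onto the Neo-Hookean matrix with zero fibril density; it is
    provided for completeness of layered models.
    """
    if name == "cartilage_frpve":
        return MaterialParams()
    if name == "meniscus_frpe":
        return MaterialParams(fibril=FibrilParams(viscoelastic=False))
    if name == "bone_linear":
        E, nu = 10e9, 0.3
        G = E / (2 * (1 + nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        return MaterialParams(
            nonfibrillar=NonFibrillarParams(G_m=G, lambda_m=lam),
            fibril=FibrilParams(E_0=0.0, E_eps=0.0, viscoelastic=False),
        )
    raise ValueError(f"unknown material preset {name!r}")
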