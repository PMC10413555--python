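import numpy as np
import pytest

from cartmech.constitutive import MaterialParams
from cartmech.fibrils import DepthProfile, assign_split_lines, build_fibril_field
from cartmech.mesh import build_layer_mesh


@pytest.fixture(scope="session")
def small_plug():
    """A 2x2x4 layered plug (10 mm x 10 mm x 2 mm) with default profiles."""
    mesh = build_layer_mesh(0.01, 0.01, 0.002, 2, 2, 1, [0.15, 0.15, 0.35, 0.35])
    profile = DepthProfile()
    split = assign_split_lines(mesh, center=[0.0051, 0.0, 0.005])
    fib = build_fibril_field(mesh, split, profile)
    return mesh, split, profile, fib


@pytest.fixture(scope="session")
def fibril_free_column():
    """1x1x20-element laterally confined biphasic column (no fibrils)."""
    from cartmech.constitutive import (FibrilParams, NonFibrillarParams,
                                       PorousParams)
    h = 1e-3
    mesh = build_layer_mesh(1e-4, 1e-4, h, 1, 1, 5, [0.25] * 4)
    profile = DepthProfile(
        fluid_fraction=lambda z: 0.8 * np.ones_like(np.asarray(z, dtype=float)),
        fibril_density=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
    )
    split = assign_split_lines(mesh, center=[5e-5, 0.0, 5e-5])
    fib = build_fibril_field(mesh, split, profile, secondary_set_size=0,
                             primary_fraction=1.0)
    params = MaterialParams(
        nonfibrillar=NonFibrillarParams(G_m=0.5e6, lambda_m=0.1e6),
        fibril=FibrilParams(E_0=0.0, E_eps=0.0, viscoelastic=False),
        porous=PorousParams(k_0=2e-15, M=0.0, n_f0=0.8),
    )
    return mesh, fib, params, h


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det fixed to +1)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def consolidation_run(fibril_free_column):
    """200 sqrt-graded steps to time factor T = 1 under a 10 kPa step load
    on the fibril-free confined column (shared across validation tests)."""
    from cartmech.analytical import consolidation_coefficient
    from cartmech.fe import (BoundaryCondition, SolverConfig, TimeSchedule,
                             solve_transient)
    mesh, fib, params, h = fibril_free_column
    nf = params.nonfibrillar
    cv = consolidation_coefficient(params.porous.k_0, nf.G_m, nf.lambda_m)
    sigma0 = 1e4
    times = (h * h / cv) * (np.arange(1, 201) / 200.0) ** 2
    bcs = [
        BoundaryCondition("displacement", "lateral", 0.0, component=0),
        BoundaryCondition("displacement", "lateral", 0.0, component=2),
        BoundaryCondition("displacement", "bottom", 0.0),
        BoundaryCondition("traction", "articular", -sigma0,
                          direction=np.array([0.0, 1.0, 0.0])),
        BoundaryCondition("pressure", "articular", 0.0),
    ]
    hist = solve_transient(mesh, fib, params, TimeSchedule(times=times), bcs,
                           config=SolverConfig(rtol=1e-9, stab_beta=0.0))
    return mesh, params, h, cv, sigma0, times, hist
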