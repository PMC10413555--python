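"""Validate the biphasic solver against 1D consolidation theory.

A fibril-free, laterally confined tissue column is loaded by a constant
10 kPa surface stress with drainage at the loaded face.  The finite
element surface settlement and basal pore pressure are compared with the
closed-form consolidation series solution.
"""

import numpy as np

from cartmech.analytical import (consolidation_coefficient,
                                 consolidation_pressure, consolidation_ratio)
from cartmech.constitutive import (FibrilParams, MaterialParams,
                                   NonFibrillarParams, PorousParams)
from cartmech.fe import BoundaryCondition, SolverConfig, TimeSchedule, solve_transient
from cartmech.fibrils import DepthProfile, assign_split_lines, build_fibril_field
from cartmech.mesh import build_layer_mesh

h = 1e-3
mesh = build_layer_mesh(1e-4, 1e-4, h, 1, 1, 5, [0.25] * 4)
profile = DepthProfile(
    fluid_fraction=lambda z: 0.8 * np.ones_like(np.asarray(z, float)),
    fibril_density=lambda z: np.zeros_like(np.asarray(z, float)))
split = assign_split_lines(mesh, center=[5e-5, 0.0, 5e-5])
fib = build_fibril_field(mesh, split, profile, 0, 1.0)
params = MaterialParams(
    nonfibrillar=NonFibrillarParams(G_m=0.5e6, lambda_m=0.1e6),
    fibril=FibrilParams(E_0=0.0, E_eps=0.0, viscoelastic=False),
    porous=PorousParams(k_0=2e-15, M=0.0, n_f0=0.8))

cv = consolidation_coefficient(2e-15, 0.5e6, 0.1e6)
sigma0 = 1e4
times = (h * h / cv) * (np.arange(1, 201) / 200.0) ** 2   # sqrt-graded to T = 1
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

top = mesh.node_set("articular")
bot = mesh.node_set("bottom")
T = cv * times / h**2
settle = np.array([-r.u[top, 1].mean() for r in hist.records])
pbase = np.array([r.p[bot].mean() for r in hist.records])
s_inf = sigma0 * h / 1.1e6

print(" T      U_fe    U_series   p_base/sig0  series")
for i in (5, 20, 60, 120, 199):
    print(f"{T[i]:5.3f}  {settle[i]/s_inf:6.4f}  {consolidation_ratio(T[i]):7.4f}"
          f"    {pbase[i]/sigma0:7.4f}   {consolidation_pressure(1.0, T[i]):7.4f}")
err_s = np.abs(settle - s_inf * consolidation_ratio(T))[3:].max() / s_inf
err_p = np.abs(pbase - sigma0 * consolidation_pressure(1.0, T))[3:].max() / sigma0
print(f"max error vs series: settlement {100*err_s:.2f}%  basal pressure {100*err_p:.2f}%")
# U is the consolidation ratio (settlement / final settlement); both the
# transient and the fully drained limit should track the series closely.
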