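# Methods

`cartmech` models the mechanical micro-environment of knee articular
cartilage during the stance phase of gait at desk scale: a
fibril-reinforced biphasic plug of tissue loaded by a rigid, frictionless
indenter whose force, position and tilt follow synthetic joint-level
loading curves.  Its outputs are the mechanoregulatory strain measures
used to flag tissue at risk of degeneration — strain in the collagen
fibril direction (SFD), maximum shear strain (MSS) and, for meniscal
tissue, the maximum principal logarithmic strain (MPS) — reduced to
volume-weighted distribution summaries, threshold-exceedance volumes and
centre-of-pressure (COP) traces.

## Tissue model

**Composition.** Cartilage is biphasic: an incompressible pore fluid in a
porous solid skeleton.  The solid combines an isotropic ground matrix
(the proteoglycan gel) and a network of collagen fibrils that carry load
in tension only.  Per material point with total fibril density
`rho(z)`, the effective (solid) Cauchy stress is

    sigma_eff = (1 - rho) * sigma_matrix + sum_d w_d sigma_f,d (e_d x e_d)

with `e_d` the current (pushed-forward, renormalised) fibril directions,
and total stress `sigma = sigma_eff - p I` with pore pressure `p`.

**Ground matrix.** Compressible Neo-Hookean,
`sigma = (G/J)(B - I) + (lambda ln J / J) I`, reducing to linear isotropic
elasticity `(G_m, lambda_m)` at small strain.  Defaults
`G_m = 0.5 MPa`, `lambda_m = 0.1 MPa`.

**Fibrils.** Each direction carries a one-dimensional tension-only
standard linear solid on the logarithmic fibril stretch
`eps_f = ln|F e_f|`: an equilibrium spring `E_0` in parallel with a
Maxwell branch `(E_eps, eta)`; backward-Euler update

    sigma_M <- (sigma_M + E_eps * d eps) / (1 + dt E_eps / eta),
    sigma_f = max(E_0 eps_f + sigma_M, 0),

with instantaneous modulus `E_0 + E_eps`, equilibrium modulus `E_0`
and relaxation time `eta / E_eps`.  Defaults `E_0 = 5 MPa`,
`E_eps = 100 MPa`, `eta = 1000 MPa s` (relaxation time 10 s).  The
meniscal variant (FRPE) is the identical network with the Maxwell branch
off; an optional strain-stiffening spring `E_0 eps + E_eps eps^2` is
available behind a switch.  The slack reset of the Maxwell history
(no tensile memory survives buckling) is applied when a converged step is
committed rather than inside the Newton iteration: an instantaneous
in-iteration reset makes the stress discontinuous in strain, which
defeats Newton during unloading, while the commit-level reset leaves the
within-step response continuous (only the mild tension-clamp kink
remains) and changes the model by at most one time step's worth of
Maxwell relaxation.

**Permeability.** Strain-dependent,
`k(J) = k_0 ((J - 1 + n_f0) / n_f0)^M`, with defaults
`k_0 = 2e-15 m^4/(N s)`, `M = 5`, and the reference fluid fraction
`n_f0` taken from the depth profile.  These constitutive forms and
constants are literature-informed defaults for healthy human cartilage,
not fitted values; all are config-overridable.

**Depth structure.** On normalised depth `z` (0 at the articular surface,
1 at bone): fluid fraction `0.90 - 0.20 z`, relative fibril density
`0.35 - 0.20 z` (both linear, overridable).  Primary fibrils follow the
classical arcade: parallel to the surface above `z_s = 0.1`, rotating
linearly in angle to surface-normal below `z_d = 0.5`.  Superficial
in-plane directions are split lines pointing toward the compartment
centre of area (unit tangent projection of centre minus point; points
under the centre fall back to the +x tangent with a warning).  A
13-direction secondary fibril set (cube edge/face/body axes — the
classical quasi-uniform family) shares 25% of the local density by
default.  All directions are built from the local geometric frame, so
the whole field is rotation-equivariant.  The mapping between mesh layers
and arcade zones is deliberately independent: zones live on `z`, not on
layer ids.

## Finite elements

Mixed u–p "soils consolidation" formulation, total Lagrangian, 8-node
hexahedra with equal-order trilinear interpolation for displacement and
pore pressure (the porous-brick element familiar from commercial codes),
2x2x2 Gauss quadrature, backward Euler in time:

    Div(J sigma F^-T) = 0
    d/dt [ J + n_f0 p / K_f ] = Div( k(J) J C^-1 Grad p ),  C = F^T F

Free-draining surfaces carry Dirichlet `p = 0`; sealed surfaces are the
natural condition.  The `n_f0 p / K_f` storage term is the physical
compressibility of the pore water (`K_f = 2.2 GPa`); it is negligible at
tissue stress levels but keeps the undrained limit well posed.

**Equal-order stabilisation.** The equal-order pair is not inf-sup stable:
in the undrained limit spurious checkerboard pressures appear.  A local
pressure-projection stabilisation (Dohrmann-Bochev type) penalises only
the intra-element pressure fluctuation `p - Pi p` with coefficient
`beta / (lambda_m + 2 G_m)`, `beta = 0.25`: checkerboard modes are
damped without any long-range artificial drainage, so the undrained
pressure support of the tissue is preserved (an earlier gradient-type
stabilisation was rejected for exactly that leakage).  Indentation-style
runs need it; resolved column consolidation runs are more accurate
without it (`stab_beta: 0`), which is how the validation analyses are
configured.

**Contact.** Frictionless rigid indenter, node-to-rigid penalty with
stiffness 1e12 Pa/m (about micron penetrations at physiological loads).
The default shape is a sphere of radius 35 mm — a femoral-condyle-like
curvature whose contact patch grows with load and stretches the
superficial network as in the joint (a flat punch is available but
compresses the fibril directions almost everywhere, which inverts the
tissue-level strain-in-fibril-direction statistics); the flat variant's
footprint edge is tapered over a 0.5 mm band with the taper stiffness in
the tangent.  The penalty law is C1-regularised over a 1e-8 m
penetration band.  Force control (target total normal force within 0.5%,
with an absolute floor of 0.5% of a tenth of the schedule peak for the
near-zero stance tails) runs as an outer bracketed secant/false-position
iteration on the indentation depth around the displacement-driven inner
solver; the first depth guess uses the undrained tissue stiffness.
Articular surface nodes inside the current footprint are sealed; the
free articular surface drains.

**Solution.** Newton's method with element-level central-difference
tangents (at the tension-clamp kink this gives the semismooth average of
the slack/taut stiffnesses), a step cap of 0.4x the minimum element edge
with backtracking on the momentum residual, modified-Newton reuse of the
factorised tangent while it contracts the residual, and symmetric Jacobi
equilibration plus one iterative-refinement pass in the sparse direct
solve (the monolithic matrix mixes stiffness, permeability and penalty
scales across ~19 orders of magnitude).  Convergence: momentum residual
below 1e-6 of the load scale (external force plus contact target), mass
residual below 1e-5 of the largest imbalance seen in the step with an
absolute floor of 1e-11 x mesh volume; iterates that stall within 50x
those tolerances (i.e. ~5e-5 of the load scale, far below the strain
resolution of interest) are accepted rather than failed.  Steps that
stall further out or invert an element are retried at half the increment
(the loading is interpolated), with regrowth after success.

## Strain metrics

Evaluated at element centroids from the centroid deformation gradient,
reported in percent:

* `MSS = max_ij |eps_p,i - eps_p,j|` over the principal values of the
  Green-Lagrange tensor `E = (F^T F - I)/2`; degeneration threshold 30%
  (proteoglycan depletion).  The absolute-value form over all three pairs
  is evaluated as written even though it equals `eps_1 - eps_3` for
  sorted values.
* `SFD = ln |F e_f|` along the local primary fibril direction; threshold
  10% (collagen degradation).  One implementation shared with the
  constitutive model.
* `MPS` = largest eigenvalue of `ln V`, `V = (F F^T)^(1/2)`; the meniscal
  measure (no threshold attached).

Summaries are volume-weighted quartiles with the averaged-inverted-CDF
convention — the unique convention that agrees *exactly* with expanding
each element into volume-many copies and taking ordinary percentiles,
which the tests pin down — plus threshold-exceedance volume fractions and
minima/maxima.  Analyses can be restricted to the tissue under the union
of contact footprints over the stance (default) or by a peak-strain
floor; the retained volume fraction is always reported, never enforced.
The COP is the force-weighted centroid of the nodal contact forces
(flagged NaN when unloaded).

## Synthetic stance-phase loading

Joint-level inputs (superior-inferior contact force, knee flexion,
anterior-posterior and medial-lateral translation, internal-external
rotation, varus-valgus moment, per-compartment COP offset) are emulated
with smooth gait-literature template curves scaled by archetype
parameters, because the subject recordings behind such musculoskeletal
pipelines are typically access-restricted.  The force channel is
double-peaked (loading response at ~25% stance, push-off at ~75%, peaks
2.5/2.2 body weights, body weight 600 N) with a C1 window forcing zero
force at the stance ends; optional smooth noise (cubic spline through a
seeded coarse Gaussian grid, 2% relative) makes repeated subjects
distinct but bit-reproducible per seed.  The KOA-like archetype applies
+15% peak force, +20% adduction-moment scale, and posterior COP shifts of
2.9 mm (lateral) / 5.1 mm (medial) — the published magnitude of the
posterior contact shift in early-stage, progressing knee OA.

What the generator does *not* emulate: inter-trial variability,
subject-specific curve shapes, kinematic-kinetic cross-correlations, and
the full six-degree-of-freedom drive of a whole-joint model (the plug
consumes force, COP offset and tilt; the remaining channels are generated
and stored for completeness and for users substituting real exported
curves via the lossless CSV round-trip).  Passing tests therefore
demonstrate the *mechanistic direction* of the healthy-vs-KOA contrast
under controlled loading differences, not subject-level magnitudes.

**Joint-to-plug force mapping.** The per-compartment force is the total
force times a medio-lateral split (default 60/40 medial-dominant) times a
`force_scale`.  The default `force_scale = 0.012` places the plug's peak
nominal compression in the 10-20% range reported for loaded knee
cartilage in vivo: the desk-scale plug lacks the osmotic swelling
pretension (out of scope here) and the surrounding loaded tissue that
stiffen cartilage in situ, so preserving the joint's full contact
pressure would drive it far beyond the tissue regime.  Setting
`force_scale: null` switches to a contact-pressure-preserving area
ratio, and `force_scale: 1` recovers the raw split force.  The
varus-valgus moment maps to indenter tilt through a compliance of
5e-4 rad/(N m).

## Pipeline and problem sizes

The default comparison runs healthy and KOA archetypes over medial and
lateral compartments on a 30 x 30 x 2.5 mm plug meshed 6 x 6 in plane
with four layers through the thickness (two finer superficial layers over
two coarser deep layers), 20 stance samples over 0.6 s.  The plug is
sized so the indenter's contact patch stays on it across the whole COP
program (including the KOA posterior shift); its lateral faces are
rollers and sealed, standing for the surrounding cartilage of a
continuous layer.  These sizes keep
a full two-subject, two-compartment comparison in the minutes range on a
single core while resolving the depth structure the metrics probe;
validation analyses (consolidation column, rheology, objectivity) use
their own prescribed sizes.  Runs are deterministic given (config, seed):
archetype seeds are derived from the global seed, iteration counts are
data-independent, and all artifacts are written with fixed float
formatting.

## Known limitations

* **Fibril-direction strain ordering.** Without osmotic swelling the
  collagen network carries no pretension, so the deep arcade fibrils —
  70% of the contact volume — lie along the compression axis and their
  strain *decreases* under heavier loading, while only the superficial
  in-plane fibrils stretch more.  The volume-weighted SFD median over
  the contact volume therefore orders healthy above KOA-like loading,
  opposite to tension-dominated (swelling-pretensioned) models; the
  superficial-layer SFD and all MSS statistics order as expected.
  Swelling is deliberately out of scope, so this inversion is a property
  of the model class and is reported as such by the validation suite
  rather than masked.
* Plug-with-indenter geometry, not a whole joint: no cartilage-cartilage
  or meniscus-cartilage deformable contact, no ligaments or bones; the
  load path is represented only by force magnitude, COP location and
  tilt.
* Equal-order u-p elements trade inf-sup stability for fidelity to the
  standard porous brick; the stabilisation controls but does not
  eliminate pressure roughness in the strongly undrained regime (strain
  metrics depend on displacement gradients only and are insensitive to
  it).
* The constitutive constants are healthy-tissue literature values; no
  disease-state parameter change is modelled (both archetypes share one
  material).
* Tension-gate and contact regularisations introduce modelling error
  bounded by the band widths (strain 1e-4; penetration 1e-8 m; 0.5 mm
  footprint edge), all far below the reported strain scales.
* The centroid evaluation of F mirrors standard practice but slightly
  smooths peak strains relative to Gauss-point extremes.
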