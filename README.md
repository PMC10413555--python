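# cartmech

Tissue-scale mechanics of knee articular cartilage under gait loading:
a fibril-reinforced biphasic (poroviscoelastic) finite-element model of
cartilage/meniscus plugs driven by synthetic stance-phase loading, with
the mechanoregulatory strain metrics used to flag tissue at risk of
degeneration in knee osteoarthritis (KOA).

## Who this is for

Computational biomechanics researchers studying how altered joint-level
loading in early KOA translates into the local tissue strains that drive
cartilage degeneration — without access to subject gait recordings or
MRI-derived knee geometries.  The package provides the whole chain at
desk scale: synthetic musculoskeletal-style loading archetypes (healthy
vs KOA-like), a transient biphasic solver with condyle-like contact, and
volume-weighted strain statistics.

## The model

Cartilage is modelled as a biphasic mixture: incompressible pore fluid in
a porous solid whose effective stress combines a compressible Neo-Hookean
proteoglycan matrix and a tension-only (visco)elastic collagen fibril
network,

    sigma = (1 - rho) sigma_NH + sum_d w_d sigma_f,d (e_d x e_d) - p I

with depth-dependent fluid fraction, fibril density and a Benninghoff
arcade fibril architecture (split lines superficially, arching to
surface-normal in the deep zone).  The coupled displacement / pore
pressure problem is solved with implicit (backward-Euler) mixed 8-node
hexahedral elements — a soils-consolidation analysis with Darcy flow and
strain-dependent permeability — under a frictionless force-controlled
rigid indenter whose force, position and tilt follow the stance-phase
program.

Three strain measures are evaluated at element centroids (in %):

* **MSS** — maximum shear strain, the largest pairwise difference of the
  principal Green-Lagrange strains (threshold 30%, proteoglycan
  depletion);
* **SFD** — strain in the fibril direction, `ln |F e_f|` (threshold 10%,
  collagen degradation);
* **MPS** — maximum principal logarithmic (Hencky) strain, the meniscal
  response measure.

They are reduced to volume-weighted quartiles, threshold-exceedance
volume fractions and centre-of-pressure (COP) traces, restricted to the
tissue under the moving contact footprint.  See `docs/methods.md` for
formulations, parameter tables and limitations.

## Worked example

```bash
python examples/03_confined_consolidation.py
```

validates the solver against the closed-form 1D consolidation series
solution and prints

```
 T      U_fe    U_series   p_base/sig0  series
0.001  0.0334   0.0339     0.9996    1.0000
0.011  0.1180   0.1185     0.9996    1.0000
0.093  0.3437   0.3442     0.9580    0.9591
0.366  0.6705   0.6715     0.5141    0.5159
1.000  0.9277   0.9313     0.1064    0.1080
max error vs series: settlement 0.36%  basal pressure 0.22%
```

`U` is the consolidation ratio (settlement over final drained
settlement) and `p_base` the excess pore pressure at the sealed base;
both track the analytical series within a fraction of a percent.  The
other examples build the plug and its collagen arcade, recover the
fibril relaxation constants, generate the gait archetypes, and run a
small healthy-vs-KOA comparison end to end (each prints what its numbers
mean).

The same pipeline is scriptable from the shell:

```bash
cartmech compare --seed 3 --out runs/demo      # healthy vs KOA, both compartments
cartmech gen-loading --archetype koa --out runs/demo
```

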