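import numpy as np
import pytest

from cartmech.analytical import (consolidation_coefficient,
                                 consolidation_pressure, consolidation_ratio)
from cartmech.constitutive import MaterialParams, MaterialState
from cartmech.fe import (BoundaryCondition, PoroelasticFE, RigidIndenter,
                         SolverConfig, TimeSchedule, solve_transient)
from cartmech.fibrils import DepthProfile, assign_split_lines, build_fibril_field
from cartmech.mesh import build_layer_mesh

from conftest import random_rotation


def _column_bcs(sigma0):
    return [
        BoundaryCondition("displacement", "lateral", 0.0, component=0),
        BoundaryCondition("displacement", "lateral", 0.0, component=2),
        BoundaryCondition("displacement", "bottom", 0.0),
        BoundaryCondition("traction", "articular", -sigma0,
                          direction=np.array([0.0, 1.0, 0.0])),
        BoundaryCondition("pressure", "articular", 0.0),
    ]


class TestScheduleValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeSchedule(times=[0.1, 0.05])

    def test_mismatched_force_length_rejected(self):
        with pytest.raises(ValueError, match="indenter_force"):
            TimeSchedule(times=[0.1, 0.2], indenter_force=[1.0])


class TestBCValidation:
    def test_conflicting_displacement_and_force(self, fibril_free_column):
        mesh, fib, params, h = fibril_free_column
        bcs = [
            BoundaryCondition("displacement", "bottom", 0.0),
            BoundaryCondition("force", "bottom", 1.0,
                              direction=np.array([0, 1.0, 0])),
        ]
        with pytest.raises(ValueError, match="both prescribed displacement"):
            PoroelasticFE(mesh, fib, params, bcs)

    def test_sealed_and_pressure_conflict(self, fibril_free_column):
        mesh, fib, params, h = fibril_free_column
        bcs = [
            BoundaryCondition("sealed", "bottom"),
            BoundaryCondition("pressure", "bottom", 0.0),
        ]
        with pytest.raises(ValueError, match="sealed"):
            PoroelasticFE(mesh, fib, params, bcs)


class TestEquilibriumAndJacobian:
    def test_zero_loading_zero_residual(self, fibril_free_column):
        mesh, fib, params, h = fibril_free_column
        solver = PoroelasticFE(mesh, fib, params, _column_bcs(0.0))
        E = mesh.n_elements
        state = MaterialState.initial(8 * E, fib.n_directions)
        ue = np.zeros((E, 8, 3))
        pe = np.zeros((E, 8))
        r, _ = solver._element_residual(ue, pe, state, np.ones(8 * E),
                                        np.zeros(8 * E), pe, 0.1)
        assert np.abs(r).max() == 0.0

    def test_jacobian_matches_directional_derivative(self):
        """FD directional derivative of the assembled residual vs K v."""
        mesh = build_layer_mesh(0.002, 0.001, 0.001, 1, 1, 1, [0.5, 0.5])
        profile = DepthProfile()
        split = assign_split_lines(mesh, center=[0.0011, 0.0, 0.0005])
        fib = build_fibril_field(mesh, split, profile)
        params = MaterialParams()
        solver = PoroelasticFE(mesh, fib, params,
                               [BoundaryCondition("displacement", "bottom", 0.0)])
        E = mesh.n_elements
        state = MaterialState.initial(8 * E, fib.n_directions)
        rng = np.random.default_rng(0)
        dof = rng.standard_normal(solver.ndof) * 1e-5
        dof[3::4] *= 1e7   # pressures at a physical scale
        Jn = np.ones(8 * E)
        pn = np.zeros(8 * E)
        pe_n = np.zeros(solver.n_nodes)[solver.conn]

        def resid(v):
            ue = np.stack([v[0::4], v[1::4], v[2::4]], 1)[solver.conn]
            pe = v[3::4][solver.conn]
            re, _ = solver._element_residual(ue, pe, state, Jn, pn, pe_n, 0.1)
            r = np.zeros(solver.ndof)
            np.add.at(r, solver.edofs.ravel(), re.ravel())
            return r

        K = solver._jacobian(dof, 0.0, state, Jn, pn, pe_n, 0.1, None, False, 1.0)
        v = rng.standard_normal(solver.ndof)
        eps = 1e-8
        lhs = (resid(dof + eps * v) - resid(dof - eps * v)) / (2 * eps)
        rhs = K @ v
        assert np.linalg.norm(lhs - rhs) <= 1e-5 * np.linalg.norm(rhs)


class TestConsolidation:
    def test_pressure_and_settlement_match_series(self, consolidation_run):
        """Transient response matches the 1D consolidation series solution."""
        mesh, params, h, cv, sigma0, times, hist = consolidation_run
        nf = params.nonfibrillar
        Mconf = nf.lambda_m + 2 * nf.G_m
        T = cv * times / h**2
        top = mesh.node_set("articular")
        bot = mesh.node_set("bottom")
        settle = np.array([-r.u[top, 1].mean() for r in hist.records])
        pbase = np.array([r.p[bot].mean() for r in hist.records])
        s_inf = sigma0 * h / Mconf
        err_s = np.abs(settle - s_inf * consolidation_ratio(T)) / s_inf
        err_p = np.abs(pbase - sigma0 * consolidation_pressure(1.0, T)) / sigma0
        assert err_s[3:].max() < 0.02
        assert err_p[3:].max() < 0.02

    def test_fluid_conservation(self, consolidation_run):
        """Outflow through the drained boundary balances the rate of volume
        change within 1% (fibril-free linear case)."""
        mesh, params, h, cv, sigma0, times, hist = consolidation_run
        top = mesh.node_set("articular")
        vol_changes = []
        outflows = []
        t_prev = 0.0
        settle_prev = 0.0
        area = 1e-4 * 1e-4
        for rec in hist.records:
            settle = -rec.u[top, 1].mean()
            vol_changes.append((settle - settle_prev) * area)
            outflows.append(rec.drain_reaction)
            settle_prev = settle
        # cumulative outflow (negative drain reaction) balances the
        # cumulative volume change
        cum_v = np.cumsum(vol_changes)
        cum_q = -np.cumsum(outflows)
        assert abs(cum_q[-1] - cum_v[-1]) <= 0.01 * abs(cum_v[-1])



class TestDrainedEquilibrium:
    def test_long_time_settlement_and_pressure(self, fibril_free_column):
        """sigma0 h / (lambda + 2G) settlement; pore pressure fully dissipated."""
        mesh, fib, params, h = fibril_free_column
        nf = params.nonfibrillar
        cv = consolidation_coefficient(params.porous.k_0, nf.G_m, nf.lambda_m)
        sigma0 = 1e3   # small load keeps the response in the linear range
        t_end = 10 * h * h / cv
        times = t_end * (np.arange(1, 41) / 40.0) ** 2
        hist = solve_transient(mesh, fib, params, TimeSchedule(times=times),
                               _column_bcs(sigma0),
                               config=SolverConfig(rtol=1e-9, stab_beta=0.0))
        top = mesh.node_set("articular")
        settle = -hist.records[-1].u[top, 1].mean()
        expected = sigma0 * h / (nf.lambda_m + 2 * nf.G_m)
        assert settle == pytest.approx(expected, rel=0.01)
        assert np.abs(hist.records[-1].p).max() < 1e-3 * sigma0


class TestTimeStepping:
    def test_zero_increment_converges_immediately(self, fibril_free_column):
        mesh, fib, params, h = fibril_free_column
        hist = solve_transient(mesh, fib, params,
                               TimeSchedule(times=[0.1, 0.2]),
                               _column_bcs(0.0))
        assert all(r.newton_iters == 0 for r in hist.records)

    def test_time_refinement_self_consistency(self, fibril_free_column):
        """Ramp on the linear material: dt and dt/2 agree within 1%."""
        mesh, fib, params, h = fibril_free_column
        nf = params.nonfibrillar
        cv = consolidation_coefficient(params.porous.k_0, nf.G_m, nf.lambda_m)
        t_end = 0.2 * h * h / cv
        sigma0 = 1e3

        def run(n):
            times = np.linspace(t_end / n, t_end, n)
            ramp = np.linspace(sigma0 / n, sigma0, n)
            bcs = [
                BoundaryCondition("displacement", "lateral", 0.0, component=0),
                BoundaryCondition("displacement", "lateral", 0.0, component=2),
                BoundaryCondition("displacement", "bottom", 0.0),
                BoundaryCondition("traction", "articular", -ramp,
                                  direction=np.array([0.0, 1.0, 0.0])),
                BoundaryCondition("pressure", "articular", 0.0),
            ]
            return solve_transient(mesh, fib, params, TimeSchedule(times=times),
                                   bcs, config=SolverConfig(rtol=1e-9, stab_beta=0.0))

        h1 = run(20)
        h2 = run(40)
        top = mesh.node_set("articular")
        s1 = -h1.records[-1].u[top, 1].mean()
        s2 = -h2.records[-1].u[top, 1].mean()
        assert s1 == pytest.approx(s2, rel=0.01)

    def test_prescribed_displacement_exact(self, fibril_free_column):
        mesh, fib, params, h = fibril_free_column
        bcs = [
            BoundaryCondition("displacement", "lateral", 0.0, component=0),
            BoundaryCondition("displacement", "lateral", 0.0, component=2),
            BoundaryCondition("displacement", "bottom", 0.0),
            BoundaryCondition("displacement", "articular", -1e-6, component=1),
            BoundaryCondition("pressure", "lateral", 0.0),
        ]
        hist = solve_transient(mesh, fib, params, TimeSchedule(times=[1.0]), bcs)
        top = mesh.node_set("articular")
        np.testing.assert_array_equal(hist.records[0].u[top, 1], -1e-6)


class TestContact:
    def _plug(self):
        mesh = build_layer_mesh(0.01, 0.01, 0.002, 4, 4, 1, [0.15, 0.15, 0.35, 0.35])
        profile = DepthProfile()
        split = assign_split_lines(mesh, center=[0.00505, 0.0, 0.005])
        fib = build_fibril_field(mesh, split, profile)
        return mesh, fib

    def _bcs(self):
        return [
            BoundaryCondition("displacement", "bottom", 0.0),
            BoundaryCondition("pressure", "articular", 0.0),
            BoundaryCondition("pressure", "lateral", 0.0),
        ]

    def test_indenter_above_surface_no_force(self):
        mesh, fib = self._plug()
        ind = RigidIndenter(center=[0.005, 0.001, 0.005], normal=[0, -1, 0],
                            axis1=[1, 0, 0], axis2=[0, 0, 1],
                            half_widths=(3e-3, 3e-3), control="displacement")
        sched = TimeSchedule(times=[0.1], indenter_depth=[0.0])
        hist = solve_transient(mesh, fib, MaterialParams(), sched, self._bcs(),
                               indenter=ind)
        assert hist.records[0].total_contact_force == 0.0

    def test_zero_force_target_rests_at_touchdown(self):
        mesh, fib = self._plug()
        ind = RigidIndenter(center=[0.005, 0.0, 0.005], normal=[0, -1, 0],
                            axis1=[1, 0, 0], axis2=[0, 0, 1],
                            half_widths=(3e-3, 3e-3), control="force")
        sched = TimeSchedule(times=[0.1], indenter_force=[0.0])
        hist = solve_transient(mesh, fib, MaterialParams(), sched, self._bcs(),
                               indenter=ind)
        assert hist.records[0].total_contact_force <= 1e-6

    def test_force_target_met_within_tolerance(self):
        mesh, fib = self._plug()
        ind = RigidIndenter(center=[0.005, 0.0, 0.005], normal=[0, -1, 0],
                            axis1=[1, 0, 0], axis2=[0, 0, 1],
                            half_widths=(3e-3, 3e-3), control="force")
        sched = TimeSchedule(times=[0.05, 0.1], indenter_force=[10.0, 25.0])
        hist = solve_transient(mesh, fib, MaterialParams(), sched, self._bcs(),
                               indenter=ind)
        for rec, target in zip(hist.records, [10.0, 25.0]):
            assert rec.total_contact_force == pytest.approx(target, rel=0.005)

    def test_flat_indenter_pressure_roughly_uniform_inside(self):
        """Flat punch on a uniform plug: interior contact pressure has a
        modest coefficient of variation (< 20%)."""
        mesh = build_layer_mesh(0.012, 0.012, 0.002, 8, 8, 1,
                                [0.15, 0.15, 0.35, 0.35])
        profile = DepthProfile()
        split = assign_split_lines(mesh, center=[0.00605, 0.0, 0.006])
        fib = build_fibril_field(mesh, split, profile)
        ind = RigidIndenter(center=[0.006, 0.0, 0.006], normal=[0, -1, 0],
                            axis1=[1, 0, 0], axis2=[0, 0, 1],
                            half_widths=(4.5e-3, 4.5e-3), control="force")
        sched = TimeSchedule(times=[0.1], indenter_force=[30.0])
        hist = solve_transient(mesh, fib, MaterialParams(), sched, self._bcs(),
                               indenter=ind)
        rec = hist.records[0]
        x = mesh.nodes[rec.contact_nodes]
        nodes, areas = mesh.nodal_areas("articular")
        area_of = dict(zip(nodes, areas))
        p = np.array([np.linalg.norm(f) / area_of[n]
                      for n, f in zip(rec.contact_nodes, rec.contact_forces)])
        interior = (np.abs(x[:, 0] - 0.006) < 2.5e-3) & \
                   (np.abs(x[:, 2] - 0.006) < 2.5e-3)
        assert interior.sum() >= 9
        cv = p[interior].std() / p[interior].mean()
        assert cv < 0.20


class TestObjectivityTranslation:
    def test_translation_invariance(self, fibril_free_column):
        """Translating the whole problem leaves strains and pressures unchanged."""
        mesh, fib, params, h = fibril_free_column
        sigma0 = 1e3
        times = [100.0, 300.0]
        hist1 = solve_transient(mesh, fib, params, TimeSchedule(times=times),
                                _column_bcs(sigma0))
        t = np.array([0.5, -0.2, 1.0])
        mesh2 = mesh.transform(None, t)
        from cartmech.fibrils import DepthProfile as DP, assign_split_lines as asl, build_fibril_field as bff
        profile = DP(fluid_fraction=lambda z: 0.8 * np.ones_like(np.asarray(z, float)),
                     fibril_density=lambda z: np.zeros_like(np.asarray(z, float)))
        split2 = asl(mesh2, center=np.array([5e-5, 0.0, 5e-5]) + t)
        fib2 = bff(mesh2, split2, profile, secondary_set_size=0,
                   primary_fraction=1.0)
        hist2 = solve_transient(mesh2, fib2, params, TimeSchedule(times=times),
                                _column_bcs(sigma0))
        np.testing.assert_allclose(hist2.records[-1].u, hist1.records[-1].u,
                                   atol=1e-12)
        np.testing.assert_allclose(hist2.records[-1].p, hist1.records[-1].p,
                                   atol=1e-9)
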