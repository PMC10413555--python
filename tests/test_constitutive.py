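import numpy as np
import pytest

from cartmech.constitutive import (FibrilDirectionState, FibrilParams,
                                   MaterialParams, MaterialState,
                                   NonFibrillarParams, PorousParams,
                                   evaluate_stress_batch, fibril_strain,
                                   fibril_stress_batch, fibril_stress_update,
                                   material_preset, neo_hookean_stress,
                                   permeability, total_stress)

from conftest import random_rotation


class TestFibrilStrain:
    def test_identity_gives_zero(self):
        assert fibril_strain(np.eye(3), [1.0, 0.0, 0.0]) == 0.0

    def test_uniaxial_stretch(self):
        F = np.diag([1.1, 1.0, 1.0])
        assert fibril_strain(F, [1, 0, 0]) == pytest.approx(np.log(1.1), abs=1e-12)

    def test_rotation_gives_zero_any_direction(self):
        R = random_rotation(11)
        rng = np.random.default_rng(0)
        for _ in range(5):
            e = rng.standard_normal(3)
            e /= np.linalg.norm(e)
            assert abs(fibril_strain(R, e)) < 1e-12

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            fibril_strain(np.eye(3), [1.0, 1.0, 0.0])


class TestNeoHookean:
    P = NonFibrillarParams(G_m=0.5e6, lambda_m=0.1e6)

    def test_reference_state_stress_free(self):
        np.testing.assert_allclose(neo_hookean_stress(np.eye(3), self.P), 0.0)

    def test_small_strain_matches_linear_elasticity(self):
        eps = 1e-6
        F = np.diag([1.0 + eps, 1.0, 1.0])
        sig = neo_hookean_stress(F, self.P)
        lin = self.P.lambda_m * eps * np.eye(3)
        lin[0, 0] += 2.0 * self.P.G_m * eps
        np.testing.assert_allclose(sig, lin, rtol=1e-4)

    def test_isotropic_stretch_gives_isotropic_stress(self):
        sig = neo_hookean_stress(1.03 * np.eye(3), self.P)
        np.testing.assert_allclose(sig, sig[0, 0] * np.eye(3), atol=1e-6)

    def test_inverted_rejected(self):
        with pytest.raises(ValueError, match="inversion"):
            neo_hookean_stress(np.diag([-1.0, 1.0, 1.0]), self.P)


class TestFibrilRheology:
    P = FibrilParams(E_0=5e6, E_eps=100e6, eta=1000e6)

    def test_compression_gives_zero_and_resets(self):
        st = FibrilDirectionState(sigma_M=1e5, eps_prev=0.01)
        s, st2 = fibril_stress_update(-0.05, st, 0.01, self.P)
        assert s == 0.0
        assert st2.sigma_M == 0.0

    def test_relaxation_constants(self):
        """Step strain held: instantaneous E_0+E_eps, equilibrium E_0,
        decay time eta/E_eps from a log-linear fit of the transient."""
        eps = 0.01
        dt = 0.05
        n = 4000   # 200 s >> tau = 10 s, so the Maxwell branch fully relaxes
        st = FibrilDirectionState()
        stresses = []
        for _ in range(n):
            s, st = fibril_stress_update(eps, st, dt, self.P)
            stresses.append(s)
        stresses = np.array(stresses)
        inst = (self.P.E_0 + self.P.E_eps) * eps
        assert stresses[0] == pytest.approx(inst, rel=0.01)
        assert stresses[-1] == pytest.approx(self.P.E_0 * eps, rel=0.01)
        # log-linear fit of the Maxwell transient
        tr = stresses - self.P.E_0 * eps
        t = dt * np.arange(1, n + 1)
        sel = tr > tr[0] * 1e-3
        slope = np.polyfit(t[sel], np.log(tr[sel]), 1)[0]
        tau = self.P.eta / self.P.E_eps
        assert -1.0 / slope == pytest.approx(tau, rel=0.02)

    def test_elastic_flag_simple_spring(self):
        P = FibrilParams(E_0=10e6, E_eps=0.0, viscoelastic=False)
        s, _ = fibril_stress_update(0.02, FibrilDirectionState(), 0.01, P)
        assert s == pytest.approx(0.2e6, abs=1e-9)

    def test_frpe_equals_frpve_with_zero_maxwell_modulus(self):
        """Identical stress trajectories when E_eps = 0."""
        rng = np.random.default_rng(5)
        eps_path = 0.03 * rng.standard_normal(50).cumsum() / 10 + 0.01
        Pv = FibrilParams(E_0=5e6, E_eps=0.0, eta=1e9, viscoelastic=True)
        Pe = FibrilParams(E_0=5e6, E_eps=0.0, viscoelastic=False)
        sv = np.zeros(1)
        ep = np.zeros(1)
        for e in eps_path:
            s_v, sv, ep = fibril_stress_batch(np.array([e]), sv, ep, 0.01, Pv)
            s_e, _, _ = fibril_stress_batch(np.array([e]), np.zeros(1),
                                            np.zeros(1), 0.01, Pe)
            np.testing.assert_allclose(s_v, s_e, atol=1e-12)

    def test_maxwell_dissipation_nonnegative_over_closed_cycle(self):
        """Discrete Maxwell-branch work over a closed strain cycle >= 0."""
        P = self.P
        t = np.linspace(0, 2 * np.pi, 400)
        eps_path = 0.02 + 0.01 * np.sin(t)       # stays taut
        dt = 0.01
        sM = np.zeros(1)
        ep = np.array([eps_path[0]])
        work = 0.0
        prev = eps_path[0]
        for e in eps_path[1:]:
            s, sM, ep = fibril_stress_batch(np.array([e]), sM, ep, dt, P)
            sM_only = sM[0]
            work += sM_only * (e - prev)
            prev = e
        assert work >= -1e-12

    def test_stress_continuous_at_zero_strain(self):
        P = self.P
        st = FibrilDirectionState(sigma_M=2e5, eps_prev=0.005)
        s_minus, _ = fibril_stress_update(-1e-12, st, 0.01, P)
        s_plus, _ = fibril_stress_update(+1e-12, st, 0.01, P)
        assert s_minus == 0.0
        assert abs(s_plus) < 1.0   # Pa; gate tapers smoothly from zero


class TestPermeability:
    P = PorousParams(k_0=2e-15, M=5.0, n_f0=0.8)

    def test_reference_state(self):
        assert permeability(1.0, self.P) == pytest.approx(2e-15)

    def test_exponent_zero_constant(self):
        P = PorousParams(k_0=2e-15, M=0.0, n_f0=0.8)
        for J in (0.5, 1.0, 1.5):
            assert permeability(J, P) == pytest.approx(2e-15)

    def test_monotone_increasing_in_J(self):
        J = np.linspace(0.4, 1.6, 40)
        k = permeability(J, self.P)
        assert np.all(np.diff(k) > 0)

    def test_compaction_limit_rejected(self):
        with pytest.raises(ValueError, match="compaction"):
            permeability(0.1, self.P)


class TestTotalStress:
    def _point(self, rho=0.3, D=4):
        rng = np.random.default_rng(2)
        dirs = rng.standard_normal((D, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = np.full(D, rho / D)
        return dirs, w

    def test_no_fibril_limit(self):
        params = MaterialParams()
        F = np.diag([1.05, 0.98, 1.0])
        dirs, _ = self._point()
        w = np.zeros(4)
        st = MaterialState.initial(1, 4)
        res, _ = total_stress(F, 2e3, dirs, w, st, 0.01, params)
        expected = neo_hookean_stress(F, params.nonfibrillar) - 2e3 * np.eye(3)
        np.testing.assert_allclose(res.total, expected, rtol=1e-12)

    def test_hydrostatic_pore_pressure_only(self):
        params = MaterialParams()
        dirs, w = self._point()
        st = MaterialState.initial(1, 4)
        res, _ = total_stress(np.eye(3), 1e3, dirs, w, st, 0.01, params)
        np.testing.assert_allclose(res.total, -1e3 * np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.total, res.effective - 1e3 * np.eye(3))

    def test_triaxial_compression_all_fibrils_slack(self):
        params = MaterialParams()
        dirs, w = self._point()
        st = MaterialState.initial(1, 4)
        F = 0.97 * np.eye(3)
        res, _ = total_stress(F, 500.0, dirs, w, st, 0.01, params)
        np.testing.assert_allclose(res.fibril_stresses, 0.0)
        expected = (1 - w.sum()) * neo_hookean_stress(F, params.nonfibrillar) \
            - 500.0 * np.eye(3)
        np.testing.assert_allclose(res.total, expected, rtol=1e-12)

    def test_objectivity(self):
        """sigma(R F) = R sigma(F) R^T for the full composite response."""
        params = MaterialParams()
        dirs, w = self._point(rho=0.35, D=6)
        rng = np.random.default_rng(9)
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        R = random_rotation(13)
        st1 = MaterialState.initial(1, 6)
        st2 = MaterialState.initial(1, 6)
        res1, _ = total_stress(F, 1e3, dirs, w, st1, 0.01, params)
        res2, _ = total_stress(R @ F, 1e3, dirs, w, st2, 0.01, params)
        np.testing.assert_allclose(res2.total, R @ res1.total @ R.T,
                                   rtol=1e-10, atol=1e-4)

    def test_symmetry(self):
        params = MaterialParams()
        dirs, w = self._point(rho=0.35, D=6)
        rng = np.random.default_rng(1)
        F = np.eye(3) + 0.04 * rng.standard_normal((3, 3))
        st = MaterialState.initial(1, 6)
        res, _ = total_stress(F, 0.0, dirs, w, st, 0.01, params)
        np.testing.assert_allclose(res.total, res.total.T, rtol=1e-12)


class TestPresets:
    def test_presets_exist_and_differ(self):
        c = material_preset("cartilage_frpve")
        m = material_preset("meniscus_frpe")
        b = material_preset("bone_linear")
        assert c.fibril.viscoelastic and not m.fibril.viscoelastic
        assert b.fibril.E_0 == 0.0 and b.nonfibrillar.G_m > 1e9

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            material_preset("steel")
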