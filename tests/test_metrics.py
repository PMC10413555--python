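import numpy as np
import pytest

from cartmech.metrics import (MetricField, SummaryStats, center_of_pressure,
                              contact_volume_filter, exceedance_fraction,
                              max_principal_log_strain, max_shear_strain,
                              metric_from_F, principal_green_lagrange,
                              volume_weighted_percentiles)

from conftest import random_rotation


class TestMaxShearStrain:
    def test_direct_evaluation(self):
        assert max_shear_strain(np.array([0.10, 0.02, -0.05])) \
            == pytest.approx(0.15, abs=1e-15)

    def test_isotropic_strain_has_no_shear(self):
        for a in (-0.2, 0.0, 0.7):
            assert max_shear_strain(np.array([a, a, a])) == 0.0

    def test_matches_bruteforce_pairwise_oracle(self):
        """MSS equals the exhaustive max over pairwise differences for
        principal strains of random symmetric tensors."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            A = rng.standard_normal((3, 3))
            E = 0.1 * (A + A.T)
            ev = np.sort(np.linalg.eigvalsh(E))[::-1]
            brute = max(abs(ev[i] - ev[j]) for i in range(3) for j in range(3))
            assert max_shear_strain(ev) == pytest.approx(brute, abs=1e-14)


class TestPrincipalAndHencky:
    def test_identity(self):
        p = principal_green_lagrange(np.eye(3))
        np.testing.assert_allclose(p.values, 0.0, atol=1e-15)
        assert max_principal_log_strain(np.eye(3)) == pytest.approx(0.0, abs=1e-15)

    def test_diagonal_stretch(self):
        F = np.diag([1.2, 0.9, 1.0])
        assert max_principal_log_strain(F) == pytest.approx(np.log(1.2), abs=1e-12)
        p = principal_green_lagrange(F)
        assert p.values[0] == pytest.approx(0.5 * (1.2**2 - 1), abs=1e-12)

    def test_left_rotation_invariance(self):
        """All three metrics are unchanged under F -> R F."""
        rng = np.random.default_rng(3)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        R = random_rotation(8)
        e = rng.standard_normal(3)
        e /= np.linalg.norm(e)
        for metric in ("mss", "mps", "sfd"):
            v1 = metric_from_F(F, metric, e)
            v2 = metric_from_F(R @ F, metric, e)
            assert v2 == pytest.approx(v1, abs=1e-10)

    def test_inverted_F_rejected(self):
        with pytest.raises(ValueError):
            max_principal_log_strain(np.diag([-1.0, 1.0, 1.0]))


class TestWeightedPercentiles:
    def _oracle(self, values, int_volumes, q):
        expanded = np.repeat(values, int_volumes)
        return np.percentile(expanded, 100 * q, method="averaged_inverted_cdf")

    def test_equal_volumes_midpoint_median(self):
        f = MetricField(values=np.array([1.0, 2.0, 3.0, 4.0]),
                        volumes=np.ones(4))
        assert volume_weighted_percentiles(f, (0.25, 0.5, 0.75)).median == 2.5

    def test_single_element_all_quantiles_equal(self):
        f = MetricField(values=np.array([7.5]), volumes=np.array([2.0]))
        s = volume_weighted_percentiles(f)
        assert s.q25 == s.median == s.q75 == 7.5

    def test_integer_volume_example(self):
        f = MetricField(values=np.array([1.0, 2.0, 3.0]),
                        volumes=np.array([1.0, 1.0, 2.0]))
        s = volume_weighted_percentiles(f)
        assert s.q75 == self._oracle(f.values, [1, 1, 2], 0.75)

    def test_matches_replication_oracle_random(self):
        """Exact agreement with integer-replication on random fixtures."""
        rng = np.random.default_rng(11)
        for trial in range(200):
            n = rng.integers(2, 12)
            values = np.round(rng.standard_normal(n) * 10, 3)
            vols = rng.integers(1, 9, size=n)
            f = MetricField(values=values, volumes=vols.astype(float))
            s = volume_weighted_percentiles(f)
            for q, got in ((0.25, s.q25), (0.5, s.median), (0.75, s.q75)):
                assert got == self._oracle(values, vols, q), (trial, q)

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal(9)
        vols = rng.integers(1, 5, size=9).astype(float)
        s1 = volume_weighted_percentiles(MetricField(values=values, volumes=vols))
        s2 = volume_weighted_percentiles(
            MetricField(values=values, volumes=1e-9 * vols))
        assert (s1.q25, s1.median, s1.q75) == (s2.q25, s2.median, s2.q75)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = rng.integers(1, 20)
            f = MetricField(values=rng.standard_normal(n),
                            volumes=rng.uniform(0.1, 3.0, n))
            s = volume_weighted_percentiles(f)
            assert s.q25 <= s.median <= s.q75
            assert s.minimum <= s.q25 and s.q75 <= s.maximum


class TestExceedance:
    def test_direct_volume_ratio(self):
        f = MetricField(values=np.array([35.0, 10.0]),
                        volumes=np.array([1.0, 3.0]))
        r = exceedance_fraction(f, 30.0)
        assert r.exceeding_fraction == pytest.approx(0.25)

    def test_all_below_gives_zero_and_tiny_threshold_gives_one(self):
        f = MetricField(values=np.array([5.0, 8.0]), volumes=np.array([1.0, 1.0]))
        assert exceedance_fraction(f, 30.0).exceeding_fraction == 0.0
        assert exceedance_fraction(f, 1e-9).exceeding_fraction == 1.0

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(23)
        f = MetricField(values=rng.uniform(0, 50, 40),
                        volumes=rng.uniform(0.5, 2.0, 40))
        fr = [exceedance_fraction(f, th).exceeding_fraction
              for th in np.linspace(1.0, 60.0, 25)]
        assert np.all(np.diff(fr) <= 1e-15)


class TestContactVolumeFilter:
    def test_full_footprint_is_noop(self):
        f = MetricField(values=np.arange(5.0) + 1, volumes=np.ones(5))
        out = contact_volume_filter(f, "footprint",
                                    footprint_mask=np.ones(5, dtype=bool))
        assert out.retained_fraction == 1.0
        np.testing.assert_array_equal(out.values, f.values)

    def test_overstrict_floor_errors(self):
        f = MetricField(values=np.array([1.0, 2.0]), volumes=np.ones(2))
        with pytest.raises(ValueError, match="retained no elements"):
            contact_volume_filter(f, "strain-floor", strain_floor_pct=99.0)

    def test_known_loaded_share(self):
        """A field where 20% of the volume is flagged loaded retains ~20%."""
        rng = np.random.default_rng(9)
        vols = np.ones(50)
        mask = np.zeros(50, dtype=bool)
        mask[:10] = True
        f = MetricField(values=rng.uniform(0, 10, 50), volumes=vols)
        out = contact_volume_filter(f, "footprint", footprint_mask=mask)
        assert out.retained_fraction == pytest.approx(0.20)


class TestCenterOfPressure:
    def test_symmetric_average(self):
        cop = center_of_pressure(np.array([2.0, 2.0]),
                                 np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                                 np.array([1.0, 1.0]))
        np.testing.assert_allclose(cop, [1.0, 0.0, 0.0])

    def test_single_loaded_face(self):
        cop = center_of_pressure(np.array([0.0, 5.0]),
                                 np.array([[0.0, 0, 0], [1.0, 2.0, 3.0]]),
                                 np.array([1.0, 1.0]))
        np.testing.assert_allclose(cop, [1.0, 2.0, 3.0])

    def test_pressure_scale_invariance(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 1.0, 6)
        x = rng.standard_normal((6, 3))
        a = rng.uniform(0.5, 2.0, 6)
        np.testing.assert_allclose(center_of_pressure(p, x, a),
                                   center_of_pressure(2.0 * p, x, a), rtol=1e-12)

    def test_zero_force_flagged(self):
        cop = center_of_pressure(np.zeros(3), np.zeros((3, 3)), np.ones(3))
        assert np.all(np.isnan(cop))


class TestSummaryValidation:
    def test_quartile_ordering_enforced(self):
        with pytest.raises(ValueError, match="quartiles"):
            SummaryStats(q25=2.0, median=1.0, q75=3.0, minimum=0.0, maximum=4.0)
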