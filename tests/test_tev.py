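import numpy as np
import pytest

from hfmaze import (
    analytic_tail_p,
    angular_sd,
    build_null,
    compute_tev,
    field_from_counts,
    jackknife_fields,
    p_value,
)
from hfmaze.displacement import StepCounts
from hfmaze.holecheck import CheckSpatialStats
from hfmaze.tev import wrap_deg


def _stats_with_restricted_mean(mean_xy, sigma_d=2.0):
    mean_xy = np.asarray(mean_xy, float)
    return CheckSpatialStats(
        n_events=10, P={0: 1.0}, mean=mean_xy, covariance=np.eye(2),
        eigvals=np.array([1.0, 1.0]), n_restricted=10,
        restricted_mean=mean_xy, restricted_covariance=np.eye(2),
        sigma_D=sigma_d,
    )


class TestAngularSd:
    def test_identical_directions_zero(self):
        v = np.tile([1.0, 2.0], (6, 1))
        assert angular_sd(v) == pytest.approx(0.0, abs=1e-9)

    def test_two_vectors_at_pm_ten_degrees(self):
        a = np.deg2rad(10.0)
        v = np.array([[np.cos(a), np.sin(a)], [np.cos(-a), np.sin(-a)]])
        assert angular_sd(v) == pytest.approx(10 * np.sqrt(2), rel=1e-9)

    def test_zero_vectors_excluded_with_warning(self):
        v = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning):
            sd = angular_sd(v)
        assert np.isfinite(sd)

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(angular_sd(np.zeros((3, 2))))

    def test_matches_null_module_statistic(self):
        """Mean S.D. of uniform-angle samples agrees between a direct
        vector-sample computation and the null generator's draws."""
        rng = np.random.default_rng(0)
        sds = []
        for _ in range(300):
            ang = rng.uniform(-np.pi, np.pi, size=8)
            v = np.column_stack([np.cos(ang), np.sin(ang)])
            sds.append(angular_sd(v))
        null = build_null(8, n_draws=20_000, seed=1, centered=True)
        assert np.mean(sds) == pytest.approx(null.sigmas.mean(), rel=0.05)


class TestNull:
    def test_cdf_properties(self):
        null = build_null(8, n_draws=5000, seed=0)
        assert p_value(null, 0.0).p == 0.0
        assert p_value(null, null.sigma_max + 1).p == 1.0
        sds = np.linspace(1, 150, 40)
        ps = [p_value(null, s).p for s in sds]
        assert all(a <= b for a, b in zip(ps[:-1], ps[1:]))

    def test_reference_significance_values(self):
        """For N=8 uniform angles, an S.D. of 30 degrees is a ~1e-4 event
        (within one order of magnitude under either null construction) and
        5 degrees is beyond 1e-7 via the analytic tail."""
        p_unc = analytic_tail_p(8, 30.0, centered=False)
        p_cen = analytic_tail_p(8, 30.0, centered=True)
        assert 1e-5 < p_unc < 1e-3
        assert 1e-5 < p_cen < 1e-3
        assert p_unc < 1e-4 < p_cen  # the two constructions bracket 1e-4
        assert analytic_tail_p(8, 5.0) <= 1e-7

    def test_tail_used_below_mc_resolution(self):
        null = build_null(8, n_draws=5000, seed=0)
        pv = p_value(null, 5.0)
        assert pv.source == "tail" and pv.p <= 1e-7

    def test_tail_matches_monte_carlo_where_both_resolve(self):
        # at S.D. ~ 60 deg the tail formula and a large MC sample agree
        null = build_null(8, n_draws=200_000, seed=3)
        mc = p_value(null, 60.0)
        assert mc.source == "mc"
        assert analytic_tail_p(8, 60.0) == pytest.approx(mc.p, rel=0.2)

    def test_invalid_inputs(self):
        null = build_null(8, n_draws=2000, seed=0)
        with pytest.raises(ValueError):
            p_value(null, -1.0)
        with pytest.raises(ValueError):
            build_null(1, n_draws=2000)
        with pytest.raises(ValueError):
            build_null(8, n_draws=10)

    def test_wrap_deg_range(self):
        a = wrap_deg([181.0, -181.0, 360.0, 540.0])
        assert np.all(a > -180.0) and np.all(a <= 180.0)


def _field_with_uniform_direction(ux, uy, L=11):
    """A field whose site vectors all point along (ux, uy)."""
    S = np.zeros((L, L, 4), dtype=int)
    S[4, 4, 0 if ux > 0 else 1] = abs(int(ux * 10)) or 0
    S[4, 4, 2 if uy > 0 else 3] = abs(int(uy * 10)) or 0
    return field_from_counts(StepCounts(L=L, S=S, ns=int(S.sum())))


class TestJackknife:
    def _sequences(self, n_mice, rng=None):
        rng = rng or np.random.default_rng(0)
        seqs = []
        for _ in range(n_mice):
            pos = np.array([6, 9])
            seq = [pos.copy()]
            for _ in range(30):
                pos = pos + [(0, -1), (1, 0), (0, -1), (-1, 0)][rng.integers(4)]
                pos = np.clip(pos, 1, 11)
                if not np.all(pos == seq[-1]):
                    seq.append(pos.copy())
            seqs.append(np.array(seq))
        return seqs

    def test_count_and_leave_one_out(self):
        seqs = self._sequences(8)
        ens = jackknife_fields(seqs, L=11)
        assert ens.N == 8 and len(ens.fields) == 8

    def test_identical_mice_identical_fields(self):
        seq = self._sequences(1)[0]
        ens = jackknife_fields([seq] * 5, L=11)
        for f in ens.fields[1:]:
            np.testing.assert_allclose(f.M, ens.fields[0].M)
        np.testing.assert_allclose(ens.mean_M, ens.fields[0].M)

    def test_mean_equals_brute_force_average(self):
        seqs = self._sequences(6)
        ens = jackknife_fields(seqs, L=11)
        direct = np.mean([f.M for f in ens.fields], axis=0)
        np.testing.assert_allclose(ens.mean_M, direct, atol=1e-12)

    def test_too_few_mice(self):
        with pytest.raises(ValueError):
            jackknife_fields(self._sequences(2), L=11)


class TestComputeTev:
    def test_aligned_fields_and_centered_checks(self):
        """All samples pointing at the target with checks on it: deviation 0
        and magnitude equal to the origin-target distance."""
        origin = np.array([0.0, 60.0])
        target = np.array([0.0, -30.0])  # straight below the start
        d = target - origin
        f = _field_with_uniform_direction(0.0, -1.0)
        from hfmaze.tev import JackknifeEnsemble

        ens = JackknifeEnsemble(N=8, fields=[f] * 8, mean_M=f.M)
        stats = _stats_with_restricted_mean(target)
        res = compute_tev(ens, stats, origin, target, n_draws=2000, seed=0)
        assert res.branch == "significant"
        assert res.deviation_deg == pytest.approx(0.0, abs=1e-6)
        assert res.magnitude == pytest.approx(np.linalg.norm(d))
        assert res.sigma_D == 2.0

    def test_significant_without_checks_falls_back(self):
        f = _field_with_uniform_direction(0.0, -1.0)
        from hfmaze.tev import JackknifeEnsemble

        ens = JackknifeEnsemble(N=8, fields=[f] * 8, mean_M=f.M)
        empty = CheckSpatialStats(
            n_events=0, P={}, mean=None, covariance=None, eigvals=None,
            n_restricted=0, restricted_mean=None, restricted_covariance=None,
            sigma_D=float("nan"),
        )
        with pytest.warns(UserWarning):
            res = compute_tev(
                ens, empty, (0.0, 60.0), (0.0, -30.0), n_draws=2000, seed=0
            )
        assert res.branch == "fallback"

    def test_direction_equivariant_under_rotation(self):
        """Rotating every input by 90 degrees rotates the TEV by 90 degrees."""
        rng = np.random.default_rng(6)
        seqs = []
        for _ in range(6):
            pos = np.array([6, 10])
            seq = [pos.copy()]
            for _ in range(25):
                pos = pos + [(0, -1), (0, -1), (1, 0)][rng.integers(3)]
                pos = np.clip(pos, 1, 11)
                if not np.all(pos == seq[-1]):
                    seq.append(pos.copy())
            seqs.append(np.array(seq))
        rot_seqs = [np.column_stack([12 - s[:, 1], s[:, 0]]) for s in seqs]
        ens = jackknife_fields(seqs, L=11)
        ens_r = jackknife_fields(rot_seqs, L=11)
        origin = np.array([0.0, 60.0])
        target = np.array([5.0, -20.0])
        stats = _stats_with_restricted_mean(target)
        stats_r = _stats_with_restricted_mean([-target[1], target[0]])
        res = compute_tev(ens, stats, origin, target, n_draws=2000, seed=0)
        res_r = compute_tev(
            ens_r, stats_r, [-origin[1], origin[0]], [-target[1], target[0]],
            n_draws=2000, seed=0,
        )
        rotated = np.array([-res.D_vec[1], res.D_vec[0]])
        np.testing.assert_allclose(res_r.D_vec, rotated, atol=1e-9)
        assert res_r.deviation_deg == pytest.approx(res.deviation_deg, abs=1e-6)
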