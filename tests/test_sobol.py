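"""Variance decomposition: design layout, estimator correctness against
closed-form oracles, bootstrap behaviour and influence flags."""

import numpy as np
import pytest

from ifascal.parameters import ParameterSpec
from ifascal.sobol import (
    SobolResult,
    bootstrap_ci,
    flag_influential_sobol,
    saltelli_sample,
    sobol_indices,
)


def _specs(k, low=0.0, high=1.0):
    return [ParameterSpec(f"x{i}", f"x{i}", "-", "kinetic",
                          0.5 * (low + high), low, high) for i in range(k)]


def _design(k, n, second_order=True, seed=0, low=0.0, high=1.0):
    return saltelli_sample(_specs(k, low, high), n=n,
                           second_order=second_order, seed=seed,
                           ranges=np.array([[low, high]] * k))


class TestDesign:
    def test_row_count_with_second_order(self):
        assert _design(4, 8).n_rows == 8 * (2 * 4 + 2)

    def test_row_count_without_second_order(self):
        assert _design(4, 8, second_order=False).n_rows == 8 * (4 + 2)

    def test_default_range_is_plus_minus_half_of_default(self):
        specs = [ParameterSpec("X52", "yield", "-", "stoichiometric",
                               0.666, 0.0, 2.0),
                 ParameterSpec("X16", "decay", "1/d", "kinetic",
                               0.62, 0.0, 2.0)]
        des = saltelli_sample(specs, n=8, seed=0)
        np.testing.assert_allclose(des.ranges[0], [0.333, 0.999])
        assert des.points[:, 0].min() >= 0.333
        assert des.points[:, 0].max() <= 0.999

    def test_same_seed_identical_design(self):
        assert np.array_equal(_design(3, 16, seed=5).points,
                              _design(3, 16, seed=5).points)

    def test_non_power_of_two_warns(self):
        with pytest.warns(UserWarning, match="power of 2"):
            _design(2, 100)

    def test_zero_width_range_rejected(self):
        specs = _specs(2)
        with pytest.raises(ValueError, match="zero-width"):
            saltelli_sample(specs, n=8, ranges=np.array([[0., 1.], [.5, .5]]))


class TestEstimators:
    def test_single_active_factor_takes_all_variance(self):
        des = _design(3, 1024, seed=1)
        res = sobol_indices(des, des.points[:, 0] ** 2)
        assert res.s1[0] == pytest.approx(1.0, abs=0.05)
        assert res.st[0] == pytest.approx(1.0, abs=0.05)
        np.testing.assert_allclose(res.s1[1:], 0.0, atol=0.05)
        np.testing.assert_allclose(res.st[1:], 0.0, atol=0.05)

    def test_additive_model_splits_variance_evenly(self):
        des = _design(2, 1024, seed=2)
        res = sobol_indices(des, des.points.sum(axis=1))
        np.testing.assert_allclose(res.s1, 0.5, atol=0.03)
        np.testing.assert_allclose(res.st, res.s1, atol=0.03)
        assert abs(res.s2[0, 1]) < 0.03

    def test_additive_total_minus_first_shrinks_with_n(self):
        gaps = []
        for n in (256, 1024, 4096):
            des = _design(2, n, seed=3)
            res = sobol_indices(des, des.points.sum(axis=1))
            gaps.append(np.max(np.abs(res.st - res.s1)))
        assert gaps[2] < gaps[0]

    def test_pure_interaction_model_satisfies_total_order_identity(self):
        """y = x1*x2 on U(-1,1): S1 ~ 0 and ST_i ~ S1_i + S2_12."""
        des = _design(2, 4096, seed=4, low=-1.0, high=1.0)
        y = des.points[:, 0] * des.points[:, 1]
        res = sobol_indices(des, y)
        np.testing.assert_allclose(res.s1, 0.0, atol=0.05)
        assert res.st[0] == pytest.approx(res.s1[0] + res.s2[0, 1], abs=0.08)
        assert res.st[0] == pytest.approx(1.0, abs=0.08)

    def test_sobol_g_function_matches_closed_form(self):
        """g-function with a = (0, 1, 4.5, 9): analytic indices within 3
        bootstrap standard errors."""
        a = np.array([0.0, 1.0, 4.5, 9.0])
        des = _design(4, 2 ** 13, seed=5)
        x = des.points
        y = np.prod((np.abs(4 * x - 2) + a) / (1 + a), axis=1)
        res = bootstrap_ci(des, y, reps=100, seed=6)
        vi = 1.0 / (3.0 * (1 + a) ** 2)
        v = np.prod(1 + vi) - 1
        s1_true = vi / v
        st_true = vi * np.prod(1 + vi) / (1 + vi) / v
        se1 = np.maximum(res.s1_ci / 1.96, 1e-4)
        set_ = np.maximum(res.st_ci / 1.96, 1e-4)
        assert np.all(np.abs(res.s1 - s1_true) <= 3 * se1)
        assert np.all(np.abs(res.st - st_true) <= 3 * set_)

    def test_zero_variance_rejected(self):
        des = _design(2, 64, seed=0)
        with pytest.raises(ValueError, match="variance"):
            sobol_indices(des, np.ones(des.n_rows))

    def test_failed_evaluations_dropped_consistently(self):
        des = _design(2, 512, seed=7)
        y = des.points.sum(axis=1)
        y[3] = np.nan                      # one base sample lost
        res = sobol_indices(des, y)
        np.testing.assert_allclose(res.s1, 0.5, atol=0.05)
        with pytest.raises(ValueError, match="dropped"):
            bad = des.points.sum(axis=1)
            bad[: des.n // 2] = np.nan
            sobol_indices(des, bad)


class TestBootstrap:
    def test_same_seed_identical_cis(self):
        des = _design(2, 256, seed=8)
        y = des.points.sum(axis=1)
        a = bootstrap_ci(des, y, reps=100, seed=3)
        b = bootstrap_ci(des, y, reps=100, seed=3)
        np.testing.assert_array_equal(a.s1_ci, b.s1_ci)
        np.testing.assert_array_equal(a.st_ci, b.st_ci)

    def test_too_few_reps_rejected(self):
        des = _design(2, 64, seed=0)
        with pytest.raises(ValueError, match="reps"):
            bootstrap_ci(des, des.points.sum(axis=1), reps=1)

    def test_coverage_of_true_first_order_index(self):
        """Additive two-factor model: the true S1 = 0.5 falls inside the 95%
        CI in at least 90% of 50 seeded replications."""
        hits = 0
        for seed in range(50):
            des = _design(2, 1024, seed=seed)
            res = bootstrap_ci(des, des.points.sum(axis=1), reps=100,
                               seed=seed + 1000)
            hits += int(np.all(np.abs(res.s1 - 0.5) <= res.s1_ci))
        assert hits >= 45


class TestInfluenceFlags:
    def _result(self, s1, st, s2=None):
        k = len(s1)
        return SobolResult(s1=np.array(s1), st=np.array(st),
                           s2=s2, variance=1.0, v_i=np.array(s1),
                           v_ij=None, n=128,
                           factor_names=tuple(f"x{i}" for i in range(k)))

    def test_threshold_boundary(self):
        rep = flag_influential_sobol(self._result([0.05, 0.04], [0.080, 0.049]))
        assert rep.influential == ["x0"]

    def test_interaction_flag_from_total_minus_first(self):
        rep = flag_influential_sobol(self._result([0.10, 0.3], [0.20, 0.31]))
        assert rep.interacting == ["x0"]

    def test_interaction_flag_from_pairwise_index(self):
        s2 = np.array([[np.nan, 0.06], [0.06, np.nan]])
        rep = flag_influential_sobol(self._result([0.2, 0.2], [0.21, 0.21], s2))
        assert rep.interacting == ["x0", "x1"]
        assert rep.pairwise is not None

    def test_strongly_negative_estimates_flagged(self):
        rep = flag_influential_sobol(self._result([-0.06, 0.5], [0.0, 0.6]))
        assert rep.suspicious_negative == ["x0"]
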