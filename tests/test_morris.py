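"""Elementary-effects screening: design bookkeeping, EE exactness on linear
models, summary statistics and thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifascal.morris import (
    elementary_effects,
    morris_summary,
    normalize_scores,
    sample_morris_design,
    screen_influential,
)


def _unit_design(k, r, seed=0, p=4):
    return sample_morris_design(k=k, r=r, ranges=[(0.0, 1.0)] * k, p=p,
                                seed=seed)


class TestDesign:
    def test_row_count_is_r_times_k_plus_one(self):
        assert _unit_design(2, 1).n_rows == 3
        assert _unit_design(68, 100).n_rows == 6900

    def test_consecutive_rows_differ_in_one_coordinate_by_delta(self):
        d = _unit_design(5, 7, seed=3)
        for t in range(d.r):
            block = d.unit_points[t * 6:(t + 1) * 6]
            diffs = np.abs(np.diff(block, axis=0))
            for row in diffs:
                nz = np.flatnonzero(row > 1e-12)
                assert len(nz) == 1
                assert row[nz[0]] == pytest.approx(d.delta)

    def test_all_points_on_p_level_grid(self):
        d = _unit_design(4, 5, seed=2)
        grid = np.arange(d.p) / (d.p - 1)
        dist = np.min(np.abs(d.unit_points[..., None] - grid), axis=-1)
        assert np.max(dist) < 1e-12

    def test_default_delta_is_two_thirds(self):
        assert _unit_design(2, 1).delta == pytest.approx(2.0 / 3.0)

    def test_same_seed_reproduces_design(self):
        a, b = _unit_design(6, 4, seed=9), _unit_design(6, 4, seed=9)
        assert np.array_equal(a.unit_points, b.unit_points)
        assert np.array_equal(a.moved_factor, b.moved_factor)

    def test_each_factor_moves_exactly_once_per_trajectory(self):
        d = _unit_design(7, 11, seed=5)
        for t in range(d.r):
            moved = d.moved_factor[t * 8 + 1:(t + 1) * 8]
            assert sorted(moved) == list(range(7))

    def test_odd_grid_levels_rejected(self):
        with pytest.raises(ValueError):
            _unit_design(2, 1, p=3)


class TestElementaryEffects:
    def test_constant_model_gives_zero_effects(self):
        d = _unit_design(3, 5)
        ee = elementary_effects(d, np.full(d.n_rows, 42.0))
        np.testing.assert_allclose(ee, 0.0, atol=1e-12)

    def test_identity_output_gives_unit_effect(self):
        d = _unit_design(3, 6, seed=1)
        ee = elementary_effects(d, d.unit_points[:, 0])
        np.testing.assert_allclose(ee[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(ee[:, 1:], 0.0, atol=1e-12)

    @given(c1=st.floats(-10, 10), c2=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_linear_model_effects_are_exact_coefficients(self, c1, c2):
        d = _unit_design(2, 4, seed=7)
        y = c1 * d.unit_points[:, 0] + c2 * d.unit_points[:, 1]
        ee = elementary_effects(d, y)
        np.testing.assert_allclose(ee[:, 0], c1, atol=1e-9)
        np.testing.assert_allclose(ee[:, 1], c2, atol=1e-9)

    def test_nonfinite_output_drops_whole_trajectory(self):
        d = _unit_design(3, 10, seed=2)
        y = d.unit_points[:, 0].copy()
        y[5] = np.nan                     # second trajectory poisoned
        ee = elementary_effects(d, y)
        assert ee.shape == (9, 3)

    def test_too_many_dropped_trajectories_refused(self):
        d = _unit_design(3, 4, seed=2)
        y = d.unit_points[:, 0].copy()
        y[::4] = np.inf
        with pytest.raises(ValueError, match="dropped"):
            elementary_effects(d, y)

    def test_output_length_mismatch_rejected(self):
        d = _unit_design(2, 2)
        with pytest.raises(ValueError, match="per design row"):
            elementary_effects(d, np.zeros(5))


class TestSummary:
    def test_hand_computed_statistics(self):
        """EE sample {2, 4}: mu = mu* = 3, sigma = sqrt(2), B = sqrt(11)."""
        res = morris_summary(np.array([[2.0], [4.0]]))
        assert res.mu[0] == pytest.approx(3.0)
        assert res.mu_star[0] == pytest.approx(3.0)
        assert res.sigma[0] == pytest.approx(np.sqrt(2.0))
        assert res.rank_score[0] == pytest.approx(np.sqrt(11.0))

    def test_sign_cancellation_motivates_mu_star(self):
        res = morris_summary(np.array([[1.0], [-1.0]]))
        assert res.mu[0] == pytest.approx(0.0)
        assert res.mu_star[0] == pytest.approx(1.0)
        assert res.polarity[0] == "+-"

    def test_constant_effects_have_zero_sigma(self):
        res = morris_summary(np.array([[-3.0], [-3.0], [-3.0]]))
        assert res.sigma[0] == pytest.approx(0.0)
        assert res.rank_score[0] == pytest.approx(3.0)
        assert res.polarity[0] == "-"

    def test_single_trajectory_refused(self):
        with pytest.raises(ValueError, match="at least 2"):
            morris_summary(np.array([[1.0, 2.0]]))

    def test_sign_flip_invariance(self, rng):
        """Flipping a factor's sign in the model flips polarity but leaves
        mu*, sigma and B unchanged."""
        ee = rng.normal(size=(20, 3)) + 1.0
        flipped = ee.copy()
        flipped[:, 1] *= -1.0
        a, b = morris_summary(ee), morris_summary(flipped)
        np.testing.assert_allclose(a.mu_star, b.mu_star)
        np.testing.assert_allclose(a.sigma, b.sigma)
        np.testing.assert_allclose(a.rank_score, b.rank_score)
        assert a.polarity[1] != b.polarity[1]

    def test_additive_linear_model_ranks_by_scaled_coefficient(self):
        """For y = sum c_i x_i over different physical ranges, sigma = 0 and
        the B-ranking equals ranking by |c_i| * range width."""
        ranges = [(0.0, 2.0), (0.0, 1.0), (0.0, 10.0)]
        coefs = np.array([3.0, -8.0, 1.0])
        d = sample_morris_design(k=3, r=12, ranges=ranges, seed=11)
        y = d.physical_points @ coefs
        res = morris_summary(elementary_effects(d, y))
        np.testing.assert_allclose(res.sigma, 0.0, atol=1e-9)
        scaled = np.abs(coefs) * np.array([hi - lo for lo, hi in ranges])
        assert list(np.argsort(res.rank)) == list(np.argsort(-scaled))


class TestNormalizationAndScreening:
    def test_affine_map_to_unit_interval(self):
        np.testing.assert_allclose(normalize_scores([1.0, 2.0, 3.0]),
                                   [0.0, 0.5, 1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_extremes_map_to_zero_and_one(self, values):
        z = normalize_scores(values)
        assert z.min() == pytest.approx(0.0)
        assert z.max() == pytest.approx(1.0)
        assert np.all((z >= 0.0) & (z <= 1.0))

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            normalize_scores([2.0, 2.0, 2.0])

    def test_threshold_boundary_is_inclusive(self, rng):
        ee = np.zeros((4, 3))
        ee[:, 0] = 1.0          # normalized mu* = 1
        ee[:, 1] = 0.1          # normalized mu* = 0.1 exactly -> included
        res = morris_summary(ee)
        rep = screen_influential(res, threshold=0.1, top_k=2)
        assert rep.influential == ["x0", "x1"]

    def test_just_below_threshold_excluded(self):
        ee = np.zeros((4, 3))
        ee[:, 0] = 1.0
        ee[:, 1] = 0.09
        rep = screen_influential(morris_summary(ee))
        assert rep.influential == ["x0"]

    def test_top_k_forwarding_count(self, rng):
        ee = rng.normal(size=(10, 68))
        rep = screen_influential(morris_summary(ee), top_k=10)
        assert len(rep.forwarded) == 10

    def test_max_factor_always_included(self, rng):
        ee = np.abs(rng.normal(size=(8, 5)))
        res = morris_summary(ee)
        rep = screen_influential(res)
        i_max = int(np.argmax(res.normalized_mu_star))
        assert f"x{i_max}" in rep.influential
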