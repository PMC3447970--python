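"""Geometry, outcome classification and the hit-probability engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import reachgain as rg
from reachgain.core_model import (
    HIT_BOTH,
    HIT_OBSTACLE_ONLY,
    HIT_TARGET_ONLY,
    MISS_BOTH,
    OBSTACLE_OFFSET_MM,
    CrossingDistribution,
    conditions_from_frame,
)


@pytest.fixture()
def cond(condition_by_id):
    return condition_by_id["T38_V-2"]


class TestConditions:
    def test_nine_cells_with_fixed_geometry(self, conditions):
        assert len(conditions) == 9
        for c in conditions:
            assert c.obstacle_edge_mm - c.target_center_mm == pytest.approx(
                OBSTACLE_OFFSET_MM
            )
            assert c.obstacle_cost_points < 0
            assert c.target_reward_points == 2.0
            assert c.target_width_mm == 6.5
        assert sorted({c.target_center_mm for c in conditions}) == [0.0, 38.0, 75.0]
        assert sorted({c.obstacle_cost_points for c in conditions}) == [-5, -2, -1]

    def test_condition_table_round_trip(self, conditions):
        frame = rg.conditions_frame(conditions)
        assert conditions_from_frame(frame) == conditions

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            rg.Condition("bad", 0.0, 6.6, obstacle_cost_points=1.0)
        with pytest.raises(ValueError):
            rg.Condition("bad", 0.0, 6.6, obstacle_cost_points=-1.0, target_width_mm=0.0)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "x1, x2, expected",
        [
            (-5.0, 0.0, HIT_TARGET_ONLY),
            (0.1, 4.0, HIT_OBSTACLE_ONLY),  # 4.0 > 6.5/2 misses the strip
            (1.0, 3.25, HIT_BOTH),  # strip boundary inclusive
            (0.0, 3.26, MISS_BOTH),  # obstacle requires strictly x1 > 0
            (-1e-12, -3.25, HIT_TARGET_ONLY),
        ],
    )
    def test_examples(self, cond, x1, x2, expected):
        assert rg.classify_outcome(x1, x2, cond) == expected

    def test_rejects_non_finite(self, cond):
        with pytest.raises(ValueError):
            rg.classify_outcome(float("nan"), 0.0, cond)
        with pytest.raises(ValueError):
            rg.classify_outcome(0.0, float("inf"), cond)

    def test_vectorized_matches_scalar(self, cond):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 3, 200)
        x2 = rng.normal(0, 3, 200)
        vec = rg.core_model.classify_outcomes(x1, x2, cond)
        scalar = [rg.classify_outcome(a, b, cond) for a, b in zip(x1, x2)]
        assert list(vec) == scalar


class TestMarginalProbabilities:
    def test_obstacle_probability_standard_normal_values(self):
        d = CrossingDistribution((0.0, 0.0), (3.0, 3.0))
        assert rg.prob_hit_obstacle(d) == pytest.approx(0.5)
        d = CrossingDistribution((-4.0, 0.0), (4.0, 3.0))
        assert rg.prob_hit_obstacle(d) == pytest.approx(1 - stats.norm.cdf(1.0))
        assert rg.prob_hit_obstacle(d) == pytest.approx(0.158655, abs=1e-6)

    def test_target_probability_standard_normal_values(self, condition_by_id):
        cond = condition_by_id["T0_V-1"]
        # centered aim with strip width = 2 sigma: Phi(1) - Phi(-1)
        d = CrossingDistribution((0.0, 0.0), (1.0, cond.target_width_mm / 2.0))
        assert rg.prob_hit_target(d, cond) == pytest.approx(0.682689, abs=1e-6)
        # very wide strip swallows everything
        wide = rg.Condition(
            "wide", 0.0, 6.6, obstacle_cost_points=-1.0, target_width_mm=1e6
        )
        assert rg.prob_hit_target(d, wide) == pytest.approx(1.0)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            CrossingDistribution((0.0, 0.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            CrossingDistribution((0.0, 0.0), (1.0, 1.0), correlation=1.0)
        with pytest.raises(ValueError):
            CrossingDistribution((float("nan"), 0.0), (1.0, 1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu=st.floats(-10, 2),
        delta=st.floats(0.01, 3),
        sigma=st.floats(1.0, 10),
    )
    def test_monotone_in_mean(self, mu, delta, sigma):
        """P(obstacle) strictly increases as the plan moves rightward."""
        lo = rg.prob_hit_obstacle(CrossingDistribution((mu, 0.0), (sigma, 1.0)))
        hi = rg.prob_hit_obstacle(CrossingDistribution((mu + delta, 0.0), (sigma, 1.0)))
        assert 0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0
        assert hi > lo

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu=st.floats(-12, -0.5),
        sigma=st.floats(2.0, 8),
        factor=st.floats(1.05, 3),
    )
    def test_more_noise_hurts_when_left_of_edge(self, mu, sigma, factor):
        """For leftward plans, inflating obstacle-plane noise raises P(hit)."""
        lo = rg.prob_hit_obstacle(CrossingDistribution((mu, 0.0), (sigma, 1.0)))
        hi = rg.prob_hit_obstacle(
            CrossingDistribution((mu, 0.0), (sigma * factor, 1.0))
        )
        assert hi > lo


class TestOutcomeProbabilities:
    def test_independence_factorization_at_zero_rho(self, cond):
        d = CrossingDistribution((-4.0, 1.0), (3.0, 2.5))
        probs = rg.outcome_probabilities(d, cond)
        p_o = rg.prob_hit_obstacle(d)
        p_t = rg.prob_hit_target(d, cond)
        assert probs["hit_both"] == pytest.approx(p_o * p_t, abs=1e-9)
        assert probs["hit_obstacle_only"] == pytest.approx(p_o * (1 - p_t), abs=1e-9)
        assert probs["hit_target_only"] == pytest.approx((1 - p_o) * p_t, abs=1e-9)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.3, 0.8])
    def test_sum_to_one_and_bounds(self, cond, rho):
        d = CrossingDistribution((-4.0, 1.0), (3.0, 3.0), correlation=rho)
        probs = rg.outcome_probabilities(d, cond)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_correlated_rectangle_against_monte_carlo(self, cond):
        """Numerical rectangle mass matches a 10^6-draw frequency oracle."""
        d = CrossingDistribution((-4.0, 1.0), (3.0, 3.0), correlation=0.3)
        n = 10**6
        xy = rg.sample_crossings(d, n, seed=42)
        hit_o = xy[:, 0] > 0
        hit_t = np.abs(xy[:, 1]) <= cond.half_width_mm
        counts = {
            "hit_both": np.mean(hit_o & hit_t),
            "hit_obstacle_only": np.mean(hit_o & ~hit_t),
            "hit_target_only": np.mean(~hit_o & hit_t),
            "miss_both": np.mean(~hit_o & ~hit_t),
        }
        probs = rg.outcome_probabilities(d, cond)
        for key, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[key] - p) < 3 * se + 1e-12, key


class TestExpectedGain:
    def test_arithmetic_identity(self):
        # V_T * P_T + V_O * P_O with P_T = 0.8, P_O = 0.1, V_T = 2, V_O = -1
        cond = rg.Condition("t", 0.0, 6.6, obstacle_cost_points=-1.0)
        # Solve for the means achieving those marginals exactly.
        s1, s2 = 2.0, 2.0
        mu1 = s1 * stats.norm.ppf(0.1)
        # symmetric strip: P_T = 2 Phi(h / s2) - 1 at mu2 = 0
        h = cond.half_width_mm
        s2 = h / stats.norm.ppf((1 + 0.8) / 2)
        d = CrossingDistribution((mu1, 0.0), (s1, s2))
        assert rg.expected_gain(d, cond) == pytest.approx(2 * 0.8 - 1 * 0.1, abs=1e-12)

    def test_reduces_to_target_term_without_cost(self):
        cond = rg.Condition(
            "t", 0.0, 6.6, obstacle_cost_points=-1e-300, target_width_mm=6.5
        )
        d = CrossingDistribution((-50.0, 0.0), (1.0, cond.half_width_mm))
        assert rg.expected_gain(d, cond) == pytest.approx(2 * 0.682689, abs=1e-4)

    @pytest.mark.parametrize("rho", [0.0, 0.3, -0.4])
    def test_invariant_under_correlation(self, cond, rho):
        """Gain is additive in the two hit events, so rho cannot matter."""
        base = rg.expected_gain(
            CrossingDistribution((-4.0, 0.5), (3.0, 2.8)), cond
        )
        other = rg.expected_gain(
            CrossingDistribution((-4.0, 0.5), (3.0, 2.8), correlation=rho), cond
        )
        assert other == pytest.approx(base, abs=1e-9)

    def test_matches_monte_carlo_average_gain(self, cond):
        d = CrossingDistribution((-3.0, 0.0), (2.5, 2.5), correlation=0.3)
        n = 10**6
        xy = rg.sample_crossings(d, n, seed=7)
        gains = cond.target_reward_points * (
            np.abs(xy[:, 1]) <= cond.half_width_mm
        ) + cond.obstacle_cost_points * (xy[:, 0] > 0)
        se = gains.std(ddof=1) / math.sqrt(n)
        assert rg.expected_gain(d, cond) == pytest.approx(gains.mean(), abs=3 * se)


class TestSampleCrossings:
    def test_reproducible_and_correct_moments(self):
        d = CrossingDistribution((-8.0, 1.0), (4.0, 2.0), correlation=0.5)
        a = rg.sample_crossings(d, 10**5, seed=11)
        b = rg.sample_crossings(d, 10**5, seed=11)
        assert np.array_equal(a, b)
        assert a.shape == (10**5, 2)
        # CLT bound on the means: 4 sigma / sqrt(n)
        for k, (mu, s) in enumerate(zip(d.mean_mm, d.sd_mm)):
            assert abs(a[:, k].mean() - mu) < 4 * s / math.sqrt(10**5)
        assert np.corrcoef(a[:, 0], a[:, 1])[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_rejects_bad_n(self):
        d = CrossingDistribution((0.0, 0.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            rg.sample_crossings(d, 0, seed=0)
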