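"""Task geometry and the expected-gain engine.

A speeded reach past a vertical obstacle toward an on-screen target is
summarized by its horizontal fingertip position at two depth planes: the
obstacle plane (halfway along the reach) and the target plane (the screen).
Coordinates are stored relative to the obstacle's left edge (``x1``,
"excursion") and the target center (``x2``, "endpoint error"), in mm.
A motor strategy fixes the mean of a bivariate Gaussian distribution of
realized crossings; the expected gain of a strategy is the reward-weighted
probability of hitting the target plus the cost-weighted probability of
passing through the obstacle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OBSTACLE_OFFSET_MM",
    "TARGET_POSITIONS_MM",
    "OBSTACLE_COSTS_POINTS",
    "TARGET_REWARD_POINTS",
    "TARGET_WIDTH_MM",
    "OUTCOMES",
    "Condition",
    "MotorStrategy",
    "CrossingDistribution",
    "TrialRecord",
    "build_conditions",
    "conditions_frame",
    "classify_outcome",
    "classify_outcomes",
    "prob_hit_obstacle",
    "prob_hit_target",
    "outcome_probabilities",
    "expected_gain",
    "sample_crossings",
]

# Experimental design constants: obstacle edge 6.6 mm right of target center,
# a 6.5 mm target strip, +2 points per target hit, costs of -1/-2/-5 points,
# targets at 0/38/75 mm right of screen center.
OBSTACLE_OFFSET_MM = 6.6
TARGET_POSITIONS_MM = (0.0, 38.0, 75.0)
OBSTACLE_COSTS_POINTS = (-1.0, -2.0, -5.0)
TARGET_REWARD_POINTS = 2.0
TARGET_WIDTH_MM = 6.5

HIT_BOTH = "hit_both"
HIT_TARGET_ONLY = "hit_target_only"
HIT_OBSTACLE_ONLY = "hit_obstacle_only"
MISS_BOTH = "miss_both"
OUTCOMES = (HIT_BOTH, HIT_TARGET_ONLY, HIT_OBSTACLE_ONLY, MISS_BOTH)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Condition:
    """One cell of the 3 (target position) x 3 (obstacle cost) design."""

    condition_id: str
    target_center_mm: float
    obstacle_edge_mm: float
    obstacle_cost_points: float
    target_reward_points: float = TARGET_REWARD_POINTS
    target_width_mm: float = TARGET_WIDTH_MM
    obstacle_location_index: int = 1

    def __post_init__(self) -> None:
        _require_finite(
            "condition geometry",
            self.target_center_mm,
            self.obstacle_edge_mm,
            self.obstacle_cost_points,
            self.target_reward_points,
            self.target_width_mm,
        )
        if self.obstacle_cost_points >= 0:
            raise ValueError("obstacle_cost_points must be negative")
        if self.target_reward_points <= 0:
            raise ValueError("target_reward_points must be positive")
        if self.target_width_mm <= 0:
            raise ValueError("target_width_mm must be positive")

    @property
    def half_width_mm(self) -> float:
        return 0.5 * self.target_width_mm


@dataclass(frozen=True)
class MotorStrategy:
    """Planned crossing coordinates: obstacle-relative excursion and
    target-relative endpoint. Leftward excursions are negative."""

    planned_excursion_mm: float
    planned_endpoint_mm: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            "strategy", self.planned_excursion_mm, self.planned_endpoint_mm
        )


@dataclass(frozen=True)
class CrossingDistribution:
    """Bivariate Gaussian over (excursion, endpoint) induced by a strategy.

    ``mean_mm`` = (mu1, mu2); ``sd_mm`` = (sigma1, sigma2); ``correlation``
    is the cross-plane correlation rho (0 in all expected-gain modeling; a
    small positive value reproduces the counterclockwise tilt of empirical
    covariance ellipses).
    """

    mean_mm: tuple[float, float]
    sd_mm: tuple[float, float]
    correlation: float = 0.0

    def __post_init__(self) -> None:
        mu1, mu2 = self.mean_mm
        s1, s2 = self.sd_mm
        _require_finite("distribution", mu1, mu2, s1, s2, self.correlation)
        if s1 <= 0 or s2 <= 0:
            raise ValueError(f"standard deviations must be positive, got {self.sd_mm}")
        if abs(self.correlation) >= 1:
            raise ValueError(f"|correlation| must be < 1, got {self.correlation}")

    @property
    def covariance(self) -> np.ndarray:
        s1, s2 = self.sd_mm
        off = self.correlation * s1 * s2
        return np.array([[s1 * s1, off], [off, s2 * s2]])


@dataclass(frozen=True)
class TrialRecord:
    """One realized reach with its outcome label."""

    subject_id: str
    condition_id: str
    block_index: int
    trial_in_block: int
    excursion_mm: float
    endpoint_mm: float
    outcome: str

    def __post_init__(self) -> None:
        _require_finite("trial coordinates", self.excursion_mm, self.endpoint_mm)
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def build_conditions(
    target_reward_points: float = TARGET_REWARD_POINTS,
    target_width_mm: float = TARGET_WIDTH_MM,
) -> list[Condition]:
    """The nine experimental conditions, ordered by location then cost."""
    conditions = []
    for loc, x_t in enumerate(TARGET_POSITIONS_MM, start=1):
        for cost in OBSTACLE_COSTS_POINTS:
            conditions.append(
                Condition(
                    condition_id=f"T{x_t:.0f}_V{cost:.0f}",
                    target_center_mm=x_t,
                    obstacle_edge_mm=x_t + OBSTACLE_OFFSET_MM,
                    obstacle_cost_points=cost,
                    target_reward_points=target_reward_points,
                    target_width_mm=target_width_mm,
                    obstacle_location_index=loc,
                )
            )
    return conditions


def conditions_frame(conditions: list[Condition] | None = None) -> pd.DataFrame:
    """Condition table as a tidy frame (one row per design cell)."""
    conditions = build_conditions() if conditions is None else conditions
    return pd.DataFrame(
        {
            "condition_id": [c.condition_id for c in conditions],
            "target_center_mm": [c.target_center_mm for c in conditions],
            "obstacle_edge_mm": [c.obstacle_edge_mm for c in conditions],
            "obstacle_cost_points": [c.obstacle_cost_points for c in conditions],
            "target_reward_points": [c.target_reward_points for c in conditions],
            "target_width_mm": [c.target_width_mm for c in conditions],
            "obstacle_location_index": [c.obstacle_location_index for c in conditions],
        }
    )


def conditions_from_frame(frame: pd.DataFrame) -> list[Condition]:
    return [
        Condition(
            condition_id=str(row.condition_id),
            target_center_mm=float(row.target_center_mm),
            obstacle_edge_mm=float(row.obstacle_edge_mm),
            obstacle_cost_points=float(row.obstacle_cost_points),
            target_reward_points=float(row.target_reward_points),
            target_width_mm=float(row.target_width_mm),
            obstacle_location_index=int(row.obstacle_location_index),
        )
        for row in frame.itertuples(index=False)
    ]


def classify_outcome(
    excursion_mm: float, endpoint_mm: float, condition: Condition
) -> str:
    """Label a realized reach.

    The obstacle is hit iff the crossing is strictly right of its edge
    (x1 > 0); the target is hit iff the endpoint lies within the strip,
    boundary inclusive (|x2| <= w/2).
    """
    _require_finite("crossing coordinates", excursion_mm, endpoint_mm)
    hit_obstacle = excursion_mm > 0.0
    hit_target = abs(endpoint_mm) <= condition.half_width_mm
    if hit_obstacle and hit_target:
        return HIT_BOTH
    if hit_obstacle:
        return HIT_OBSTACLE_ONLY
    if hit_target:
        return HIT_TARGET_ONLY
    return MISS_BOTH


def classify_outcomes(
    excursion_mm: np.ndarray, endpoint_mm: np.ndarray, condition: Condition
) -> np.ndarray:
    """Vectorized :func:`classify_outcome` for arrays of crossings."""
    x1 = np.asarray(excursion_mm, dtype=float)
    x2 = np.asarray(endpoint_mm, dtype=float)
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("crossing coordinates must be finite")
    hit_o = x1 > 0.0
    hit_t = np.abs(x2) <= condition.half_width_mm
    out = np.where(
        hit_o & hit_t,
        HIT_BOTH,
        np.where(hit_o, HIT_OBSTACLE_ONLY, np.where(hit_t, HIT_TARGET_ONLY, MISS_BOTH)),
    )
    return out


def prob_hit_obstacle(d: CrossingDistribution) -> float:
    """P(x1 > 0): Gaussian mass right of the obstacle edge."""
    mu1, _ = d.mean_mm
    s1, _ = d.sd_mm
    return float(stats.norm.cdf(mu1 / s1))


def prob_hit_target(d: CrossingDistribution, condition: Condition) -> float:
    """P(|x2| <= w/2): Gaussian mass inside the target strip."""
    _, mu2 = d.mean_mm
    _, s2 = d.sd_mm
    h = condition.half_width_mm
    return float(stats.norm.cdf((h - mu2) / s2) - stats.norm.cdf((-h - mu2) / s2))


def outcome_probabilities(
    d: CrossingDistribution, condition: Condition
) -> dict[str, float]:
    """Joint probabilities of the four outcomes.

    With rho = 0 the obstacle and target events are independent and the
    joint probabilities are products of marginals; otherwise the rectangle
    P(x1 > 0, |x2| <= w/2) is integrated numerically under the bivariate
    Gaussian.
    """
    p_o = prob_hit_obstacle(d)
    p_t = prob_hit_target(d, condition)
    h = condition.half_width_mm
    if d.correlation == 0.0:
        p_both = p_o * p_t
    else:
        mvn = stats.multivariate_normal(mean=np.asarray(d.mean_mm), cov=d.covariance)
        upper = np.array([np.inf, h])
        lower = np.array([0.0, -h])
        p_both = float(mvn.cdf(upper, lower_limit=lower))
        if not math.isfinite(p_both):
            raise FloatingPointError(
                "bivariate rectangle integration failed: "
                f"mean={d.mean_mm}, sd={d.sd_mm}, rho={d.correlation}"
            )
    probs = {
        HIT_BOTH: p_both,
        HIT_OBSTACLE_ONLY: p_o - p_both,
        HIT_TARGET_ONLY: p_t - p_both,
        MISS_BOTH: 1.0 - p_o - p_t + p_both,
    }
    # Clip the tiny negative values quadrature can leave in extreme tails.
    probs = {k: min(1.0, max(0.0, v)) for k, v in probs.items()}
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise FloatingPointError(f"outcome probabilities sum to {total}, not 1")
    return probs


def expected_gain(d: CrossingDistribution, condition: Condition) -> float:
    """Expected points per reach: V_T * P(target) + V_O * P(obstacle).

    The gain is additive in the two hit indicators, so it depends only on
    the marginal probabilities and is invariant to rho.
    """
    return condition.target_reward_points * prob_hit_target(
        d, condition
    ) + condition.obstacle_cost_points * prob_hit_obstacle(d)


def sample_crossings(
    d: CrossingDistribution,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` (x1, x2) crossing pairs; returns an (n, 2) array."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s1, s2 = d.sd_mm
    rho = d.correlation
    z = rng.standard_normal((n, 2))
    x1 = d.mean_mm[0] + s1 * z[:, 0]
    x2 = d.mean_mm[1] + s2 * (rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1])
    return np.column_stack([x1, x2])
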