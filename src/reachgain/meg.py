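"""Expected-gain curves over theoretical excursions and the MEG excursion.

For a condition with fitted sigma lines, every theoretical planned
excursion e' (<= 0, left of the obstacle edge) implies a crossing
distribution: mean (e', mean endpoint error), SDs from the sigma lines,
rho = 0. Scanning e' traces the expected-cost, expected-reward and
expected-gain curves; the maximizer e* is the prediction of the optimal
(maximum-expected-gain) reach planner for that condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core_model import (
    Condition,
    CrossingDistribution,
    expected_gain,
    prob_hit_obstacle,
    prob_hit_target,
)
from .sigma_model import SigmaModel, predict_sigma

__all__ = ["GridSpec", "EGCurve", "eg_curve", "optimize_excursion", "predicted_vs_observed"]

#: Grid agreement tolerance used by the optimizer refinement (points).
_REFINE_XATOL = 1e-4


@dataclass(frozen=True)
class GridSpec:
    """Excursion search grid: [lo_mm, hi_mm] at step_mm spacing, clipped to
    the sigma-positive range of the condition's fitted lines."""

    lo_mm: float = -40.0
    hi_mm: float = 0.0
    step_mm: float = 0.1


@dataclass(frozen=True)
class EGCurve:
    condition_id: str
    excursion_mm: np.ndarray
    expected_cost: np.ndarray
    expected_reward: np.ndarray
    expected_gain: np.ndarray
    meg_excursion_mm: float
    gain_at_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": self.condition_id,
                "excursion_mm": self.excursion_mm,
                "expected_cost": self.expected_cost,
                "expected_reward": self.expected_reward,
                "expected_gain": self.expected_gain,
            }
        )


def _distribution_at(
    condition: Condition,
    sigma_model: SigmaModel,
    endpoint_mean_mm: float,
    excursion_mm: float,
) -> CrossingDistribution:
    loc = condition.obstacle_location_index
    return CrossingDistribution(
        mean_mm=(excursion_mm, endpoint_mean_mm),
        sd_mm=(
            predict_sigma(sigma_model, loc, "obstacle", excursion_mm),
            predict_sigma(sigma_model, loc, "target", excursion_mm),
        ),
        correlation=0.0,
    )


def strategy_gain(
    condition: Condition,
    sigma_model: SigmaModel,
    endpoint_mean_mm: float,
    excursion_mm: float,
) -> float:
    """Expected gain of planning excursion ``excursion_mm`` in ``condition``."""
    d = _distribution_at(condition, sigma_model, endpoint_mean_mm, excursion_mm)
    return expected_gain(d, condition)


def _admissible_interval(
    condition: Condition, sigma_model: SigmaModel, grid: GridSpec
) -> tuple[float, float]:
    lo, hi = sigma_model.admissible_range(
        condition.obstacle_location_index, grid.lo_mm, grid.hi_mm
    )
    # Stay strictly inside the sigma-positive range.
    eps = 1e-9
    return lo + eps, hi - eps if hi < grid.hi_mm else hi


def eg_curve(
    condition: Condition,
    sigma_model: SigmaModel,
    endpoint_mean_mm: float = 0.0,
    grid: GridSpec = GridSpec(),
) -> EGCurve:
    """Expected cost / reward / gain over the admissible excursion grid."""
    lo, hi = _admissible_interval(condition, sigma_model, grid)
    n = int(np.floor((hi - lo) / grid.step_mm)) + 1
    if n < 2:
        raise ValueError(
            f"admissible excursion grid for {condition.condition_id} is empty"
        )
    e = hi - grid.step_mm * np.arange(n)[::-1]
    cost = np.empty(n)
    reward = np.empty(n)
    for i, ei in enumerate(e):
        d = _distribution_at(condition, sigma_model, endpoint_mean_mm, ei)
        cost[i] = condition.obstacle_cost_points * prob_hit_obstacle(d)
        reward[i] = condition.target_reward_points * prob_hit_target(d, condition)
    gain = cost + reward
    e_star = optimize_excursion(condition, sigma_model, endpoint_mean_mm, grid)
    return EGCurve(
        condition_id=condition.condition_id,
        excursion_mm=e,
        expected_cost=cost,
        expected_reward=reward,
        expected_gain=gain,
        meg_excursion_mm=e_star,
        gain_at_max=strategy_gain(condition, sigma_model, endpoint_mean_mm, e_star),
    )


def optimize_excursion(
    condition: Condition,
    sigma_model: SigmaModel,
    endpoint_mean_mm: float = 0.0,
    grid: GridSpec = GridSpec(),
) -> float:
    """MEG excursion e*: coarse 0.5 mm grid scan + bounded scalar refinement.

    Flat maxima are resolved toward the smallest |e*| (minimal-deviation
    convention).
    """
    lo, hi = _admissible_interval(condition, sigma_model, grid)
    coarse = np.arange(hi, lo - 1e-12, -0.5)  # scanned from 0 leftward
    gains = np.array(
        [strategy_gain(condition, sigma_model, endpoint_mean_mm, e) for e in coarse]
    )
    best = int(np.argmax(gains))  # first max in scan order = closest to 0
    e0 = coarse[best]
    a = max(lo, e0 - 0.5)
    b = min(hi, e0 + 0.5)
    res = optimize.minimize_scalar(
        lambda e: -strategy_gain(condition, sigma_model, endpoint_mean_mm, e),
        bounds=(a, b),
        method="bounded",
        options={"xatol": _REFINE_XATOL},
    )
    e_star = float(res.x)
    # Keep the refinement honest: never return worse than the coarse best.
    if -res.fun < gains[best]:
        e_star = float(e0)
    return e_star


def predicted_vs_observed(
    observed: pd.DataFrame, meg_results: pd.DataFrame
) -> pd.DataFrame:
    """Pair each condition's observed mean excursion with its MEG prediction.

    Parameters
    ----------
    observed
        Per-condition observed summaries with columns ``condition_id``,
        ``mean_excursion_mm`` and ``se_excursion_mm`` (across-subject SE).
    meg_results
        Per-condition MEG table with columns ``condition_id`` and
        ``meg_excursion_mm``.
    """
    obs_ids = set(observed["condition_id"])
    pred_ids = set(meg_results["condition_id"])
    if obs_ids != pred_ids:
        raise ValueError(
            f"condition mismatch: only-observed={sorted(obs_ids - pred_ids)}, "
            f"only-predicted={sorted(pred_ids - obs_ids)}"
        )
    merged = observed.merge(
        meg_results[["condition_id", "meg_excursion_mm"]], on="condition_id"
    )
    out = merged[
        ["condition_id", "mean_excursion_mm", "se_excursion_mm", "meg_excursion_mm"]
    ].rename(
        columns={
            "mean_excursion_mm": "observed_excursion_mm",
            "se_excursion_mm": "observed_se_mm",
            "meg_excursion_mm": "predicted_excursion_mm",
        }
    )
    out["ci95_halfwidth_mm"] = 1.96 * out["observed_se_mm"]
    return out.reset_index(drop=True)
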