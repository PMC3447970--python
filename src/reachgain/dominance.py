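"""The Dominance Test for expected-gain maximization.

A subject's observed strategies form an empirical menu of movement plans
known to be available. Cross-applying the strategy observed in condition j
to every condition i (same costs and sigma lines as i, strategy j's
obstacle-relative excursion) yields a gain matrix G[i][j]. If some
off-diagonal entry in row i beats the diagonal, the strategy actually used
in condition i was demonstrably suboptimal: a plan the subject exhibits
elsewhere would have earned more here. No model of all possible strategies
is needed — only the ones actually observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import Condition
from .meg import strategy_gain
from .sigma_model import SigmaModel

__all__ = ["DominanceResult", "cross_condition_gain_matrix", "dominance_test"]

#: Default margin (points) above the diagonal required to flag dominance.
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class DominanceResult:
    gain_matrix: pd.DataFrame  # rows: condition applied in; cols: strategy from
    own_gain: pd.Series
    dominated: pd.Series  # bool per condition
    margin_points: pd.Series  # best off-diagonal gain minus own gain
    best_alternative: pd.Series  # condition id of the best competing strategy

    @property
    def n_dominated(self) -> int:
        return int(self.dominated.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": self.own_gain.index,
                "own_gain": self.own_gain.values,
                "dominated": self.dominated.values,
                "margin_points": self.margin_points.values,
                "best_alternative": self.best_alternative.values,
            }
        )


def cross_condition_gain_matrix(
    observed: pd.DataFrame,
    sigma_model: SigmaModel,
    conditions: list[Condition],
) -> pd.DataFrame:
    """G[i][j]: expected gain in condition i of the strategy observed in j.

    ``observed`` needs columns ``condition_id``, ``mean_excursion_mm`` and
    ``mean_endpoint_mm``. Strategies transfer as obstacle-relative
    excursions; the endpoint mean is taken from the *applied-in* condition
    i (endpoint bias travels with the target, not the strategy). Entries
    whose excursion falls outside condition i's sigma-positive range are
    NaN (not-evaluable), never extrapolated to sigma <= 0.
    """
    cond_map = {c.condition_id: c for c in conditions}
    missing = set(cond_map) - set(observed["condition_id"])
    if missing:
        raise ValueError(f"observed strategies missing for conditions: {sorted(missing)}")
    obs = observed.set_index("condition_id")
    ids = [c.condition_id for c in conditions]
    G = pd.DataFrame(index=pd.Index(ids, name="applied_in"),
                     columns=pd.Index(ids, name="strategy_from"), dtype=float)
    for i in ids:
        cond_i = cond_map[i]
        endpoint_i = float(obs.loc[i, "mean_endpoint_mm"])
        for j in ids:
            excursion_j = float(obs.loc[j, "mean_excursion_mm"])
            try:
                G.loc[i, j] = strategy_gain(cond_i, sigma_model, endpoint_i, excursion_j)
            except ValueError:
                G.loc[i, j] = np.nan  # outside condition i's admissible range
    return G


def dominance_test(
    gain_matrix: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> DominanceResult:
    """Flag conditions whose own strategy is beaten by another observed one.

    Condition i is dominated iff max_j G[i][j] - G[i][i] > epsilon, with
    not-evaluable (NaN) entries excluded from the max. The margin is
    reported for every condition (negative or ~0 when not dominated).
    """
    G = gain_matrix
    ids = list(G.index)
    own = pd.Series([G.loc[i, i] for i in ids], index=ids, name="own_gain")
    if own.isna().any():
        raise ValueError("diagonal (own-strategy) gains must be evaluable")
    margins = []
    best_alt = []
    for i in ids:
        row = G.loc[i].drop(labels=[i]).dropna()
        if len(row) == 0:
            margins.append(float("-inf"))
            best_alt.append("")
            continue
        j = row.idxmax()
        margins.append(float(row.max() - own[i]))
        best_alt.append(j)
    margins = pd.Series(margins, index=ids, name="margin_points")
    dominated = pd.Series(
        [m > epsilon for m in margins], index=ids, name="dominated"
    )
    return DominanceResult(
        gain_matrix=G,
        own_gain=own,
        dominated=dominated,
        margin_points=margins,
        best_alternative=pd.Series(best_alt, index=ids, name="best_alternative"),
    )


def bootstrap_dominance(
    trials: pd.DataFrame,
    sigma_model: SigmaModel,
    conditions: list[Condition],
    n_boot: int = 200,
    epsilon: float = DEFAULT_EPSILON,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-condition fraction of trial-resampled replicates flagged dominated.

    Auxiliary uncertainty measure: trials are resampled with replacement
    within each condition, observed strategies recomputed, and the
    dominance test repeated. Headline flags remain the point-estimate ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [c.condition_id for c in conditions]
    counts = pd.Series(0, index=ids, dtype=float)
    groups = {cid: grp for cid, grp in trials.groupby("condition_id")}
    for _ in range(n_boot):
        rows = []
        for cid in ids:
            grp = groups[cid]
            idx = rng.integers(0, len(grp), size=len(grp))
            sample = grp.iloc[idx]
            rows.append(
                {
                    "condition_id": cid,
                    "mean_excursion_mm": float(sample["excursion_mm"].mean()),
                    "mean_endpoint_mm": float(sample["endpoint_mm"].mean()),
                }
            )
        G = cross_condition_gain_matrix(pd.DataFrame(rows), sigma_model, conditions)
        res = dominance_test(G, epsilon)
        counts += res.dominated.astype(float)
    return pd.DataFrame(
        {"condition_id": ids, "dominated_fraction": (counts / n_boot).values}
    )
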