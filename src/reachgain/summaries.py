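"""Condition-level summary statistics of crossing data.

Two pooling modes mirror how value-diagram figures are typically built:

``pooled``
    Each subject's trials are first centered on that subject's own
    condition mean, then second moments (SDs, correlation) are pooled
    across subjects; reported means are pooled across all trials.
``per_subject``
    Summaries are computed within subject and then averaged; standard
    errors are taken across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize_conditions"]

_REQUIRED = {"subject_id", "condition_id", "excursion_mm", "endpoint_mm"}


def _check(trials: pd.DataFrame) -> None:
    missing = _REQUIRED - set(trials.columns)
    if missing:
        raise ValueError(f"trials missing columns: {sorted(missing)}")
    counts = trials.groupby("condition_id").size()
    too_small = counts[counts < 2]
    if len(too_small):
        raise ValueError(
            f"conditions with fewer than 2 trials: {list(too_small.index)}"
        )


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def summarize_conditions(
    trials: pd.DataFrame, pooling: str = "pooled"
) -> pd.DataFrame:
    """One summary row per condition (sample SDs use the n-1 denominator).

    Columns: condition_id, n_trials, mean_excursion_mm, mean_endpoint_mm,
    sd_excursion_mm, sd_endpoint_mm, se_excursion_mm, se_endpoint_mm,
    correlation_hat, n_subjects, pooled_over.
    """
    if pooling not in ("pooled", "per_subject"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    _check(trials)

    rows = []
    for cid, grp in trials.groupby("condition_id", sort=True):
        subjects = sorted(grp["subject_id"].unique())
        n = len(grp)
        if pooling == "pooled":
            # Center within subject, pool second moments across subjects.
            cx = grp["excursion_mm"] - grp.groupby("subject_id")["excursion_mm"].transform("mean")
            cy = grp["endpoint_mm"] - grp.groupby("subject_id")["endpoint_mm"].transform("mean")
            sd1 = float(np.std(cx, ddof=1))
            sd2 = float(np.std(cy, ddof=1))
            rows.append(
                {
                    "condition_id": cid,
                    "n_trials": n,
                    "mean_excursion_mm": float(grp["excursion_mm"].mean()),
                    "mean_endpoint_mm": float(grp["endpoint_mm"].mean()),
                    "sd_excursion_mm": sd1,
                    "sd_endpoint_mm": sd2,
                    "se_excursion_mm": sd1 / np.sqrt(n),
                    "se_endpoint_mm": sd2 / np.sqrt(n),
                    "correlation_hat": _corr(cx.to_numpy(), cy.to_numpy()),
                    "n_subjects": len(subjects),
                    "pooled_over": ";".join(subjects),
                }
            )
        else:
            per = grp.groupby("subject_id").agg(
                m1=("excursion_mm", "mean"),
                m2=("endpoint_mm", "mean"),
                s1=("excursion_mm", lambda v: np.std(v, ddof=1)),
                s2=("endpoint_mm", lambda v: np.std(v, ddof=1)),
            )
            corr = grp.groupby("subject_id").apply(
                lambda g: _corr(g["excursion_mm"].to_numpy(), g["endpoint_mm"].to_numpy()),
                include_groups=False,
            )
            k = len(per)
            se_div = np.sqrt(k) if k > 1 else np.nan
            rows.append(
                {
                    "condition_id": cid,
                    "n_trials": n,
                    "mean_excursion_mm": float(per["m1"].mean()),
                    "mean_endpoint_mm": float(per["m2"].mean()),
                    "sd_excursion_mm": float(per["s1"].mean()),
                    "sd_endpoint_mm": float(per["s2"].mean()),
                    "se_excursion_mm": float(per["m1"].std(ddof=1) / se_div)
                    if k > 1
                    else float("nan"),
                    "se_endpoint_mm": float(per["m2"].std(ddof=1) / se_div)
                    if k > 1
                    else float("nan"),
                    "correlation_hat": float(corr.mean()),
                    "n_subjects": k,
                    "pooled_over": ";".join(subjects),
                }
            )
    out = pd.DataFrame(rows)
    return out.reset_index(drop=True)


def attach_condition_columns(
    summaries: pd.DataFrame, conditions: pd.DataFrame
) -> pd.DataFrame:
    """Merge obstacle_location_index / cost columns onto a summary table."""
    cols = ["condition_id", "obstacle_location_index", "obstacle_cost_points",
            "target_center_mm"]
    return summaries.merge(conditions[cols], on="condition_id", validate="one_to_one")
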