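"""Model-comparison evidence and data-quality diagnostics.

Evidence for the optimal-planning hypothesis is expressed in decibels,
10*log10 of the posterior odds between two accounts of the predicted-vs-
observed excursion scatter: M0, the identity line (observed = predicted,
the signature of an agent maximizing expected gain), and M1, a free
slope/intercept line with uniform priors. 3 dB corresponds to 2:1 odds;
3-4.75 dB (2:1 to 3:1) is the conventional floor for significant evidence.

The remaining diagnostics check the modeling assumptions: stationarity of
excursions within blocks (no "homing in"), absence of trial-to-trial
autocorrelation up to lag 15, and Gaussianity of crossing coordinates via
QQ agreement with standard-normal quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "EvidenceResult",
    "db_from_odds",
    "odds_from_db",
    "unity_line_evidence",
    "block_position_profile",
    "autocorrelation",
    "qq_gaussian",
]


def db_from_odds(odds: float) -> float:
    """Evidence in decibels: 10*log10(odds). Odds of 2:1 -> 3.01 dB."""
    if not (odds > 0) or not math.isfinite(odds):
        raise ValueError(f"odds must be positive and finite, got {odds!r}")
    return 10.0 * math.log10(odds)


def odds_from_db(db: float) -> float:
    """Posterior odds implied by evidence in decibels (inverse of
    :func:`db_from_odds`)."""
    if not math.isfinite(db):
        raise ValueError(f"dB value must be finite, got {db!r}")
    return 10.0 ** (db / 10.0)


@dataclass(frozen=True)
class EvidenceResult:
    """Evidence for the identity-line model M0 over the free-line model M1."""

    evidence_db: float
    odds: float
    log_marginal_m0: float
    log_marginal_m1: float
    slope_range: tuple[float, float]
    intercept_range: tuple[float, float]
    n_points: int

    @property
    def prior_spec(self) -> str:
        return (
            f"M0: slope 1, intercept 0 (no free parameters); "
            f"M1: slope ~ U{self.slope_range}, intercept ~ U{self.intercept_range} mm"
        )


def _gaussian_loglik(
    observed: np.ndarray, predicted_line: np.ndarray, se: np.ndarray
) -> np.ndarray:
    # Sum over points of log N(observed; line, se); broadcasts over leading axes.
    resid = (observed - predicted_line) / se
    return np.sum(-0.5 * resid**2 - np.log(se) - 0.5 * np.log(2 * np.pi), axis=-1)


def unity_line_evidence(
    predicted: np.ndarray,
    observed: np.ndarray,
    se: np.ndarray,
    slope_range: tuple[float, float] = (0.0, 2.0),
    intercept_range: tuple[float, float] = (-20.0, 20.0),
    n_grid: int = 201,
) -> EvidenceResult:
    """Bayesian evidence (dB) that observed excursions lie on the identity line.

    Observations are modelled as Gaussian around the model line with known
    per-point SDs equal to their standard errors. M0 (identity line) has no
    free parameters, so its marginal likelihood is the plain likelihood.
    M1 marginalizes a free slope and intercept over independent uniform
    priors by trapezoidal integration on an ``n_grid`` x ``n_grid`` grid.
    Positive dB favors the identity line; the sign flips when the models
    are exchanged.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (predicted.shape == observed.shape == se.shape):
        raise ValueError("predicted, observed and se must have matching shapes")
    n = predicted.size
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("per-point standard errors must be positive and finite")

    log_m0 = float(_gaussian_loglik(observed, predicted, se))

    # A zero-width range degenerates to a point prior in that dimension.
    def _axis(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray, float]:
        if hi < lo:
            raise ValueError(f"invalid prior range ({lo}, {hi})")
        if hi == lo:
            return np.array([lo]), np.array([0.0]), 0.0
        pts = np.linspace(lo, hi, n_grid)
        logw = np.log(np.r_[0.5, np.ones(n_grid - 2), 0.5])
        # trapezoid step and prior normalization cancel to log(step/width)
        return pts, logw, np.log((pts[1] - pts[0]) / (hi - lo))

    slopes, logw_a, lognorm_a = _axis(*slope_range)
    intercepts, logw_b, lognorm_b = _axis(*intercept_range)
    a = slopes[:, None, None]
    b = intercepts[None, :, None]
    loglik = _gaussian_loglik(observed, a * predicted + b, se)
    log_m1 = float(
        logsumexp(loglik + logw_a[:, None] + logw_b[None, :])
        + lognorm_a
        + lognorm_b
    )

    evidence_db = 10.0 / np.log(10.0) * (log_m0 - log_m1)
    return EvidenceResult(
        evidence_db=float(evidence_db),
        odds=float(10.0 ** (evidence_db / 10.0)),
        log_marginal_m0=log_m0,
        log_marginal_m1=log_m1,
        slope_range=tuple(slope_range),
        intercept_range=tuple(intercept_range),
        n_points=n,
    )


def block_position_profile(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean block-centered excursion at each within-block trial position.

    Each block's mean is removed before averaging across blocks and
    subjects, so a flat profile near zero indicates stationarity (no
    within-block learning or homing-in). The returned frame carries the
    per-position means and SEs plus, in ``attrs``, the slope (mm per trial
    position) of a straight-line fit to the profile and its SE.
    """
    required = {"subject_id", "block_index", "trial_in_block", "excursion_mm"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials missing columns: {sorted(missing)}")
    centered = trials.copy()
    centered["centered_mm"] = centered["excursion_mm"] - centered.groupby(
        ["subject_id", "block_index"]
    )["excursion_mm"].transform("mean")
    positions = np.sort(trials["trial_in_block"].unique())
    expected = np.arange(positions.min(), positions.max() + 1)
    if not np.array_equal(positions, expected):
        raise ValueError("within-block trial positions have gaps")
    prof = (
        centered.groupby("trial_in_block")["centered_mm"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_centered_mm", "sem": "se_mm", "count": "n"})
    )
    x = prof["trial_in_block"].to_numpy(dtype=float)
    y = prof["mean_centered_mm"].to_numpy(dtype=float)
    coef, cov = np.polyfit(x, y, deg=1, cov=True)
    prof.attrs["slope_mm_per_trial"] = float(coef[0])
    prof.attrs["slope_se"] = float(np.sqrt(cov[0, 0]))
    return prof


def autocorrelation(series: np.ndarray, max_lag: int = 15) -> pd.DataFrame:
    """Sample autocorrelations up to ``max_lag`` with white-noise bounds.

    Uses the biased (1/n) normalization, for which the conventional
    +-1.96/sqrt(n) white-noise bounds apply. Lag 0 is included and equals
    1 exactly.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) <= max_lag + 1:
        raise ValueError(f"series length {len(x)} too short for max_lag={max_lag}")
    if np.std(x) == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    r = _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)
    bound = 1.96 / math.sqrt(len(x))
    out = pd.DataFrame(
        {
            "lag": np.arange(max_lag + 1),
            "autocorrelation": r,
            "lower_bound": -bound,
            "upper_bound": bound,
        }
    )
    out["significant"] = np.abs(out["autocorrelation"]) > bound
    out.loc[0, "significant"] = False  # lag 0 is identically 1
    return out


def qq_gaussian(
    values: np.ndarray, plotting_positions: str = "midpoint"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Standard-normal QQ pairs and their linearity (correlation) coefficient.

    Values are standardized (mean 0, SD 1), sorted, and paired with
    standard-normal quantiles at plotting positions (i - 0.5)/n
    (``midpoint``, default) or i/(n + 1) (``weibull``). Gaussian data give
    a coefficient near 1; heavy tails pull it down.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 values, got {n}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("QQ plot undefined for zero-variance data")
    z = np.sort((x - np.mean(x)) / sd)
    i = np.arange(1, n + 1)
    if plotting_positions == "midpoint":
        p = (i - 0.5) / n
    elif plotting_positions == "weibull":
        p = i / (n + 1.0)
    else:
        raise ValueError(f"unknown plotting_positions {plotting_positions!r}")
    theoretical = stats.norm.ppf(p)
    linearity = float(np.corrcoef(theoretical, z)[0, 1])
    return theoretical, z, linearity
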