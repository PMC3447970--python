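"""Linear model of fingertip positional uncertainty vs excursion.

Reach variability at both critical depth planes grows as trajectories
detour further around the obstacle. Six straight lines — one per obstacle
location (3) and plane (obstacle, target) — relate the empirical standard
deviation of crossings to the signed mean excursion. Lines are fit by
weighted least squares and used to predict uncertainty at theoretical
(unobserved) excursions when computing expected-gain curves. Lines are
parameterized on signed excursion (negative = leftward), so slopes are
typically negative: larger detours, larger spread. No cross-location
pooling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PLANES", "LineFit", "SigmaModel", "fit_sigma_lines", "predict_sigma"]

PLANES = ("obstacle", "target")

#: Predictions at or below this sigma (mm) are treated as outside the
#: trustworthy extrapolation range of a fitted line.
MIN_SIGMA_MM = 0.05


@dataclass(frozen=True)
class LineFit:
    intercept_mm: float
    slope: float  # mm of SD per mm of signed excursion
    r_squared: float = float("nan")
    intercept_se: float = float("nan")
    slope_se: float = float("nan")
    n_points: int = 0
    fit_weights: str = "1/SE(sigma)^2"


class SigmaModel:
    """Six fitted lines keyed by (obstacle_location_index, plane)."""

    def __init__(self, lines: dict[tuple[int, str], LineFit]):
        for (loc, plane) in lines:
            if plane not in PLANES:
                raise ValueError(f"unknown plane {plane!r}")
        self.lines = dict(lines)

    @classmethod
    def from_coefficients(
        cls, coefficients: dict[tuple[int, str], tuple[float, float]]
    ) -> "SigmaModel":
        """Build from {(location, plane): (intercept_mm, slope)} pairs."""
        return cls(
            {key: LineFit(intercept_mm=a, slope=b) for key, (a, b) in coefficients.items()}
        )

    def line(self, obstacle_location_index: int, plane: str) -> LineFit:
        try:
            return self.lines[(obstacle_location_index, plane)]
        except KeyError:
            raise KeyError(
                f"no fitted line for location {obstacle_location_index}, plane {plane!r}"
            ) from None

    def predict(
        self, obstacle_location_index: int, plane: str, excursion_mm: float
    ) -> float:
        return predict_sigma(self, obstacle_location_index, plane, excursion_mm)

    def admissible_range(
        self,
        obstacle_location_index: int,
        lo_mm: float = -40.0,
        hi_mm: float = 0.0,
        min_sigma_mm: float = MIN_SIGMA_MM,
    ) -> tuple[float, float]:
        """Excursion interval where both planes predict sigma > min_sigma_mm."""
        lo, hi = lo_mm, hi_mm
        for plane in PLANES:
            f = self.line(obstacle_location_index, plane)
            if f.slope < 0:
                # sigma decreases toward 0 excursion: a + b*e > m  =>  e < (m-a)/b
                bound = (min_sigma_mm - f.intercept_mm) / f.slope
                hi = min(hi, bound)
            elif f.slope > 0:
                bound = (min_sigma_mm - f.intercept_mm) / f.slope
                lo = max(lo, bound)
            elif f.intercept_mm <= min_sigma_mm:
                raise ValueError(
                    f"line ({obstacle_location_index}, {plane}) predicts "
                    f"sigma <= {min_sigma_mm} mm everywhere"
                )
        if lo >= hi:
            raise ValueError(
                f"empty admissible excursion range for location {obstacle_location_index}"
            )
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (loc, plane), f in sorted(self.lines.items()):
            rows.append(
                {
                    "obstacle_location_index": loc,
                    "plane": plane,
                    "intercept_mm": f.intercept_mm,
                    "slope": f.slope,
                    "r_squared": f.r_squared,
                    "intercept_se": f.intercept_se,
                    "slope_se": f.slope_se,
                    "n_points": f.n_points,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SigmaModel":
        lines = {}
        for row in frame.itertuples(index=False):
            lines[(int(row.obstacle_location_index), str(row.plane))] = LineFit(
                intercept_mm=float(row.intercept_mm),
                slope=float(row.slope),
                r_squared=float(getattr(row, "r_squared", float("nan"))),
                intercept_se=float(getattr(row, "intercept_se", float("nan"))),
                slope_se=float(getattr(row, "slope_se", float("nan"))),
                n_points=int(getattr(row, "n_points", 0)),
            )
        return cls(lines)


def _sd_standard_error(sd: np.ndarray, n: np.ndarray) -> np.ndarray:
    # Delta-method SE of a Gaussian sample SD: s / sqrt(2 (n - 1)).
    return sd / np.sqrt(2.0 * (n - 1.0))


def fit_sigma_lines(summaries: pd.DataFrame) -> SigmaModel:
    """Fit the six sigma-vs-excursion lines from condition summaries.

    Parameters
    ----------
    summaries
        One row per condition (pooled over subjects) with columns
        ``obstacle_location_index``, ``mean_excursion_mm``,
        ``sd_excursion_mm``, ``sd_endpoint_mm`` and ``n_trials``. The three
        obstacle-cost levels at each location provide the points for that
        location's two lines.

    Each line regresses the sample SD on the signed mean excursion with
    weights 1/SE(sigma)^2, where SE(sigma) = s/sqrt(2(n-1)).
    """
    required = {
        "obstacle_location_index",
        "mean_excursion_mm",
        "sd_excursion_mm",
        "sd_endpoint_mm",
        "n_trials",
    }
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")

    sd_col = {"obstacle": "sd_excursion_mm", "target": "sd_endpoint_mm"}
    lines: dict[tuple[int, str], LineFit] = {}
    for loc, grp in summaries.groupby("obstacle_location_index"):
        if len(grp) < 2:
            raise ValueError(
                f"need >= 2 summary points per obstacle location, "
                f"got {len(grp)} for location {loc}"
            )
        e = grp["mean_excursion_mm"].to_numpy(dtype=float)
        n = grp["n_trials"].to_numpy(dtype=float)
        for plane in PLANES:
            sd = grp[sd_col[plane]].to_numpy(dtype=float)
            se = _sd_standard_error(sd, n)
            if np.any(se <= 0) or not np.all(np.isfinite(se)):
                raise ValueError(
                    f"non-positive SD standard errors for location {loc}, plane {plane}"
                )
            X = sm.add_constant(e)
            res = sm.WLS(sd, X, weights=1.0 / se**2).fit()
            lines[(int(loc), plane)] = LineFit(
                intercept_mm=float(res.params[0]),
                slope=float(res.params[1]),
                r_squared=float(res.rsquared),
                intercept_se=float(res.bse[0]),
                slope_se=float(res.bse[1]),
                n_points=len(grp),
            )
    return SigmaModel(lines)


def predict_sigma(
    model: SigmaModel, obstacle_location_index: int, plane: str, excursion_mm: float
) -> float:
    """Predicted SD (mm) at a theoretical excursion; errors outside the
    range where the line stays positive."""
    f = model.line(obstacle_location_index, plane)
    sigma = f.intercept_mm + f.slope * excursion_mm
    if sigma <= 0:
        raise ValueError(
            f"predicted sigma {sigma:.3f} mm <= 0 at excursion {excursion_mm} mm "
            f"(location {obstacle_location_index}, plane {plane}): outside the "
            "trustworthy extrapolation range"
        )
    return float(sigma)
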