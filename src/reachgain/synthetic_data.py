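"""Synthetic obstacle-avoidance experiments.

Generates complete per-trial crossing data with the statistical structure
the analysis pipeline assumes: 7 subjects, the 3 target-position x 3
obstacle-cost design, 4 blocks of 30 reaches per condition (1080 reaches
per subject), bivariate Gaussian crossings whose SDs grow linearly with
planned excursion magnitude, and an optional small positive cross-plane
correlation.

The simulated agent's policy is configurable: ``optimal`` plans the MEG
excursion for each condition under the ground-truth sigma lines;
``scaled`` plans a fixed fraction kappa of it (kappa = 0.8 emulates an
agent stopping 80% of the way between the obstacle edge and the MEG
excursion); ``fixed`` uses user-supplied per-condition excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    TARGET_POSITIONS_MM,
    Condition,
    build_conditions,
    classify_outcomes,
    conditions_frame,
)
from .meg import GridSpec, optimize_excursion
from .sigma_model import SigmaModel

__all__ = [
    "GeneratorConfig",
    "default_sigma_model",
    "build_design",
    "policy_excursions",
    "simulate_experiment",
]

#: Ground-truth sigma-line coefficients used by default. Intercepts grow
#: with target eccentricity (longer, faster reaches are noisier) and
#: slopes are sized so sigma roughly doubles over a 20 mm leftward
#: excursion, with target-plane lines a little shallower at the farther
#: locations (detours inflate obstacle-plane spread more than endpoint
#: spread as the movement re-converges onto the target). The coefficients
#: were chosen once, by design, so that (a) the nine MEG excursions span
#: about -5 to -14 mm with every pairwise gap at least ~3 standard errors
#: of a pooled condition mean (distinct optima across the design, as in
#: the study), and (b) the sigma-vs-excursion signal across each
#: location's three cost levels is 7-8.5 times the sampling error of a
#: pooled SD estimate, which centers the fitted-line R-squared
#: distribution inside the 0.8-0.99 band typical of such fits.
DEFAULT_SIGMA_COEFFICIENTS: dict[tuple[int, str], tuple[float, float]] = {
    (1, "obstacle"): (3.4, -0.165),
    (1, "target"): (3.4, -0.165),
    (2, "obstacle"): (3.7, -0.158),
    (2, "target"): (3.7, -0.148),
    (3, "obstacle"): (3.9, -0.169),
    (3, "target"): (3.9, -0.133),
}


def default_sigma_model() -> SigmaModel:
    """Ground-truth sigma lines used by the generator by default."""
    return SigmaModel.from_coefficients(DEFAULT_SIGMA_COEFFICIENTS)


@dataclass
class GeneratorConfig:
    """Study-design and agent parameters for one synthetic experiment."""

    n_subjects: int = 7
    blocks_per_condition: int = 4
    trials_per_block: int = 30
    policy: str = "optimal"  # optimal | scaled | fixed
    policy_scale: float = 1.0  # kappa, used when policy == "scaled"
    fixed_excursions_mm: dict[str, float] | None = None  # used when policy == "fixed"
    sigma_coefficients: dict[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_COEFFICIENTS)
    )
    endpoint_bias_mm: dict[float, float] = field(
        default_factory=lambda: {x: 0.0 for x in TARGET_POSITIONS_MM}
    )
    correlation: float = 0.0
    between_subject_sd_mm: float = 0.0
    ar1_coefficient: float = 0.0  # nonzero only to exercise the autocorrelation check

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.blocks_per_condition, self.trials_per_block) < 1:
            raise ValueError("design counts must be positive")
        if self.policy not in ("optimal", "scaled", "fixed"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "scaled" and not (0.0 < self.policy_scale <= 1.0):
            raise ValueError("policy_scale (kappa) must be in (0, 1]")
        if self.policy == "fixed" and not self.fixed_excursions_mm:
            raise ValueError("fixed policy requires fixed_excursions_mm")
        if abs(self.correlation) >= 1:
            raise ValueError("|correlation| must be < 1")
        if abs(self.ar1_coefficient) >= 1:
            raise ValueError("|ar1_coefficient| must be < 1")

    def sigma_model(self) -> SigmaModel:
        return SigmaModel.from_coefficients(self.sigma_coefficients)

    # -- plain-text (YAML) round trip -------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_subjects": self.n_subjects,
            "blocks_per_condition": self.blocks_per_condition,
            "trials_per_block": self.trials_per_block,
            "policy": self.policy,
            "policy_scale": self.policy_scale,
            "fixed_excursions_mm": self.fixed_excursions_mm,
            "sigma_coefficients": {
                f"{loc}:{plane}": [a, b]
                for (loc, plane), (a, b) in self.sigma_coefficients.items()
            },
            "endpoint_bias_mm": {float(k): float(v) for k, v in self.endpoint_bias_mm.items()},
            "correlation": self.correlation,
            "between_subject_sd_mm": self.between_subject_sd_mm,
            "ar1_coefficient": self.ar1_coefficient,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "sigma_coefficients" in data:
            coeffs = {}
            for key, (a, b) in data["sigma_coefficients"].items():
                loc, plane = key.split(":")
                coeffs[(int(loc), plane)] = (float(a), float(b))
            data["sigma_coefficients"] = coeffs
        if "endpoint_bias_mm" in data:
            data["endpoint_bias_mm"] = {
                float(k): float(v) for k, v in data["endpoint_bias_mm"].items()
            }
        return cls(**data)


def build_design(
    config: GeneratorConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition table plus a blocked, per-subject randomized trial schedule.

    Returns ``(conditions, schedule)`` where ``schedule`` has one row per
    trial with subject_id, block_index (1-based within subject),
    trial_in_block and condition_id. Each condition appears in
    ``blocks_per_condition`` blocks of ``trials_per_block`` reaches; block
    order is shuffled independently per subject.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = build_conditions()
    cond_frame = conditions_frame(conditions)
    cond_ids = np.array([c.condition_id for c in conditions])
    n_blocks = len(cond_ids) * config.blocks_per_condition
    tpb = config.trials_per_block
    frames = []
    for s in range(1, config.n_subjects + 1):
        blocks = np.repeat(cond_ids, config.blocks_per_condition)
        rng.shuffle(blocks)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{s:02d}",
                    "block_index": np.repeat(np.arange(1, n_blocks + 1), tpb),
                    "trial_in_block": np.tile(np.arange(1, tpb + 1), n_blocks),
                    "condition_id": np.repeat(blocks, tpb),
                }
            )
        )
    schedule = pd.concat(frames, ignore_index=True)
    return cond_frame, schedule


def policy_excursions(
    config: GeneratorConfig,
    sigma_model: SigmaModel,
    conditions: list[Condition] | None = None,
) -> pd.DataFrame:
    """Planned strategy per condition under the configured policy.

    Returns a frame with condition_id, planned_excursion_mm and
    planned_endpoint_mm. The optimal policy plans the MEG excursion e*
    under the supplied (ground-truth) sigma lines; the scaled policy plans
    kappa * e*; the fixed policy uses user values. The planned endpoint is
    the configured per-target bias.
    """
    conditions = build_conditions() if conditions is None else conditions
    if config.policy in ("optimal", "scaled") and sigma_model is None:
        raise ValueError(f"{config.policy} policy requires a sigma model")
    kappa = 1.0 if config.policy == "optimal" else config.policy_scale
    rows = []
    for c in conditions:
        endpoint = config.endpoint_bias_mm.get(c.target_center_mm, 0.0)
        if config.policy == "fixed":
            try:
                e = config.fixed_excursions_mm[c.condition_id]
            except KeyError:
                raise ValueError(
                    f"fixed policy missing excursion for {c.condition_id}"
                ) from None
        else:
            e_star = optimize_excursion(c, sigma_model, endpoint, GridSpec())
            e = kappa * e_star
        rows.append((c.condition_id, float(e), float(endpoint)))
    return pd.DataFrame(
        rows, columns=["condition_id", "planned_excursion_mm", "planned_endpoint_mm"]
    )


def simulate_experiment(
    config: GeneratorConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Simulate a full experiment; one row per reach.

    Crossings are drawn from the bivariate Gaussian implied by the policy
    strategy and the ground-truth sigma lines evaluated at the planned
    excursion; outcomes are labelled from the realized coordinates and the
    condition geometry. Trials are independent within blocks unless an
    AR(1) coefficient is set (a switch that exists to exercise the
    autocorrelation diagnostic); subject-level policy heterogeneity adds
    Gaussian jitter to each subject's planned excursions when enabled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_model = config.sigma_model()
    conditions = {c.condition_id: c for c in build_conditions()}
    _, schedule = build_design(config, rng)
    plans = policy_excursions(config, sigma_model, list(conditions.values()))
    plans = plans.set_index("condition_id")

    rho = config.correlation
    phi = config.ar1_coefficient
    tpb = config.trials_per_block

    # Per-(subject, condition) policy jitter, drawn once up front so that all
    # blocks of a condition share one planned excursion per subject.
    subjects = sorted(schedule["subject_id"].unique())
    offsets = pd.DataFrame(0.0, index=subjects, columns=sorted(conditions))
    if config.between_subject_sd_mm > 0:
        offsets.loc[:, :] = rng.standard_normal(offsets.shape) * config.between_subject_sd_mm

    x1 = np.empty(len(schedule))
    x2 = np.empty(len(schedule))
    outcome = np.empty(len(schedule), dtype=object)
    # Blocks are contiguous runs of `tpb` rows; draws are grouped by
    # condition (in sorted order) so the noise stream is reproducible.
    for cid in sorted(conditions):
        cond = conditions[cid]
        loc = cond.obstacle_location_index
        mask = (schedule["condition_id"] == cid).to_numpy()
        n = int(mask.sum())
        mu1 = (
            plans.loc[cid, "planned_excursion_mm"]
            + offsets.loc[schedule.loc[mask, "subject_id"], cid].to_numpy()
        )
        mu2 = float(plans.loc[cid, "planned_endpoint_mm"])
        bad = np.unique(np.round(mu1, 6))
        for m in bad:
            f_o = sigma_model.line(loc, "obstacle")
            f_t = sigma_model.line(loc, "target")
            if (f_o.intercept_mm + f_o.slope * m) <= 0 or (
                f_t.intercept_mm + f_t.slope * m
            ) <= 0:
                raise ValueError(
                    f"non-positive sigma at planned excursion {m} mm "
                    f"in condition {cid}"
                )
        s1 = sigma_model.line(loc, "obstacle")
        s2 = sigma_model.line(loc, "target")
        sig1 = s1.intercept_mm + s1.slope * mu1
        sig2 = s2.intercept_mm + s2.slope * mu1
        z = rng.standard_normal((n, 2))
        if phi != 0.0:
            z = _ar1_filter_blocks(z, phi, tpb)
        e1 = sig1 * z[:, 0]
        e2 = sig2 * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1])
        x1[mask] = mu1 + e1
        x2[mask] = mu2 + e2
        outcome[mask] = classify_outcomes(x1[mask], x2[mask], cond)

    trials = schedule.copy()
    trials["excursion_mm"] = x1
    trials["endpoint_mm"] = x2
    trials["outcome"] = outcome
    return trials[
        [
            "subject_id",
            "condition_id",
            "block_index",
            "trial_in_block",
            "excursion_mm",
            "endpoint_mm",
            "outcome",
        ]
    ]


def _ar1_filter_blocks(z: np.ndarray, phi: float, trials_per_block: int) -> np.ndarray:
    """IID standard normals -> unit-variance AR(1) series, restarted at each
    block boundary (rows are contiguous blocks of ``trials_per_block``)."""
    n = len(z)
    if n % trials_per_block != 0:
        raise ValueError("rows are not whole blocks")
    shaped = z.reshape(-1, trials_per_block, 2).copy()
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, trials_per_block):
        shaped[:, t] = phi * shaped[:, t - 1] + scale * shaped[:, t]
    return shaped.reshape(n, 2)
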