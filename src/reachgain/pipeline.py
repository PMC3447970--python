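"""End-to-end orchestration: simulate -> summarize -> fit sigma lines ->
MEG -> dominance -> evidence -> diagnostics.

All randomness flows from a single top-level seed through named
per-stage substreams, so a rerun with the same config and seed reproduces
every output file byte-for-byte. The run manifest records the config hash,
seed and SHA256 of each output; the manifest hash covers exactly those
(stage timings are reported but excluded), so identical reruns hash
identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_model import build_conditions, conditions_frame
from .diagnostics import (
    autocorrelation,
    block_position_profile,
    qq_gaussian,
    unity_line_evidence,
)
from .dominance import cross_condition_gain_matrix, dominance_test
from .meg import GridSpec, eg_curve, optimize_excursion, predicted_vs_observed
from .sigma_model import fit_sigma_lines
from .summaries import attach_condition_columns, summarize_conditions
from .synthetic_data import GeneratorConfig, simulate_experiment

__all__ = ["run_all", "stage_seed"]

_STAGES = (
    "simulate",
    "summarize",
    "fit_sigma",
    "meg",
    "dominance",
    "evidence",
    "diagnostics",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_all(
    config: GeneratorConfig | str | Path,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Run the full analysis pipeline; returns the run manifest.

    Writes under ``out_dir``: trials.csv, conditions.csv, summary
    tables, the fitted sigma model, EG curves, the predicted-vs-observed
    table, the dominance matrix and flags, the evidence result, the
    stationarity/autocorrelation/QQ diagnostics, a report.json with the
    headline quantities, and manifest.json.
    """
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    config_hash = _sha256(config_path)

    conditions = build_conditions()
    cond_frame = conditions_frame(conditions)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name: str):
        timings[name] = time.perf_counter()
        return stage_seed(seed, name)

    def _done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]

    # -- simulate ----------------------------------------------------------
    s = _stage("simulate")
    trials = simulate_experiment(config, seed=s)
    outputs["conditions"] = out / "conditions.csv"
    _write_csv(cond_frame, outputs["conditions"])
    outputs["trials"] = out / "trials.csv"
    _write_csv(trials, outputs["trials"])
    _done("simulate")

    # -- summarize ---------------------------------------------------------
    _stage("summarize")
    pooled = attach_condition_columns(summarize_conditions(trials, "pooled"), cond_frame)
    per_subject = attach_condition_columns(
        summarize_conditions(trials, "per_subject"), cond_frame
    )
    outputs["summary_pooled"] = out / "summary_pooled.csv"
    outputs["summary_per_subject"] = out / "summary_per_subject.csv"
    _write_csv(pooled, outputs["summary_pooled"])
    _write_csv(per_subject, outputs["summary_per_subject"])
    _done("summarize")

    # -- fit sigma lines ---------------------------------------------------
    _stage("fit_sigma")
    sigma_fit = fit_sigma_lines(pooled)
    outputs["sigma_fit"] = out / "sigma_fit.csv"
    _write_csv(sigma_fit.to_frame(), outputs["sigma_fit"])
    _done("fit_sigma")

    # -- MEG ---------------------------------------------------------------
    _stage("meg")
    endpoint_means = pooled.set_index("condition_id")["mean_endpoint_mm"]
    curves = []
    meg_rows = []
    for c in conditions:
        mu2 = float(endpoint_means[c.condition_id])
        curve = eg_curve(c, sigma_fit, mu2, GridSpec())
        curves.append(curve.to_frame())
        meg_rows.append(
            {
                "condition_id": c.condition_id,
                "meg_excursion_mm": curve.meg_excursion_mm,
                "gain_at_max": curve.gain_at_max,
            }
        )
    meg_table = pd.DataFrame(meg_rows)
    outputs["eg_curves"] = out / "eg_curves.csv"
    outputs["meg"] = out / "meg.csv"
    _write_csv(pd.concat(curves, ignore_index=True), outputs["eg_curves"])
    _write_csv(meg_table, outputs["meg"])
    # Across-subject means/SEs for the predicted-vs-observed comparison.
    pvo = predicted_vs_observed(
        per_subject[["condition_id", "mean_excursion_mm", "se_excursion_mm"]],
        meg_table,
    )
    outputs["predicted_vs_observed"] = out / "predicted_vs_observed.csv"
    _write_csv(pvo, outputs["predicted_vs_observed"])
    _done("meg")

    # -- dominance ---------------------------------------------------------
    _stage("dominance")
    G = cross_condition_gain_matrix(
        pooled[["condition_id", "mean_excursion_mm", "mean_endpoint_mm"]],
        sigma_fit,
        conditions,
    )
    dom = dominance_test(G)
    outputs["dominance_matrix"] = out / "dominance_matrix.csv"
    outputs["dominance_flags"] = out / "dominance_flags.csv"
    G.to_csv(outputs["dominance_matrix"], float_format="%.10g")
    _write_csv(dom.to_frame(), outputs["dominance_flags"])
    _done("dominance")

    # -- evidence ----------------------------------------------------------
    _stage("evidence")
    ev = unity_line_evidence(
        pvo["predicted_excursion_mm"].to_numpy(),
        pvo["observed_excursion_mm"].to_numpy(),
        pvo["observed_se_mm"].to_numpy(),
    )
    outputs["evidence"] = out / "evidence.json"
    outputs["evidence"].write_text(
        json.dumps(
            {
                "evidence_db": ev.evidence_db,
                "odds": ev.odds,
                "log_marginal_m0": ev.log_marginal_m0,
                "log_marginal_m1": ev.log_marginal_m1,
                "prior_spec": ev.prior_spec,
                "n_points": ev.n_points,
            },
            indent=2,
        )
        + "\n"
    )
    _done("evidence")

    # -- diagnostics -------------------------------------------------------
    _stage("diagnostics")
    profile = block_position_profile(trials)
    outputs["block_profile"] = out / "block_profile.csv"
    _write_csv(profile, outputs["block_profile"])
    acf_rows = []
    for (subject, block), grp in trials.groupby(["subject_id", "block_index"]):
        series = grp.sort_values("trial_in_block")["excursion_mm"].to_numpy()
        ac = autocorrelation(series, max_lag=15)
        ac.insert(0, "subject_id", subject)
        ac.insert(1, "block_index", block)
        acf_rows.append(ac)
    acf_table = pd.concat(acf_rows, ignore_index=True)
    outputs["autocorrelations"] = out / "autocorrelations.csv"
    _write_csv(acf_table, outputs["autocorrelations"])
    qq_rows = []
    for cid, grp in trials.groupby("condition_id"):
        for col, plane in (("excursion_mm", "obstacle"), ("endpoint_mm", "target")):
            theo, emp, r = qq_gaussian(grp[col].to_numpy())
            qq_rows.append(
                {"condition_id": cid, "plane": plane, "linearity": r, "n": len(grp)}
            )
    qq_table = pd.DataFrame(qq_rows)
    outputs["qq_linearity"] = out / "qq_linearity.csv"
    _write_csv(qq_table, outputs["qq_linearity"])
    _done("diagnostics")

    # -- report and manifest ----------------------------------------------
    lagged = acf_table[acf_table["lag"] > 0]
    report = {
        "n_conditions": int(len(cond_frame)),
        "n_trials": int(len(trials)),
        "predicted_vs_observed": pvo.to_dict(orient="records"),
        "n_dominated_conditions": dom.n_dominated,
        "evidence_db": ev.evidence_db,
        "block_profile_slope_mm_per_trial": profile.attrs["slope_mm_per_trial"],
        "autocorr_significant_fraction": float(lagged["significant"].mean()),
        "qq_linearity_min": float(qq_table["linearity"].min()),
    }
    outputs["report"] = out / "report.json"
    outputs["report"].write_text(json.dumps(report, indent=2) + "\n")

    hashes = {name: _sha256(path) for name, path in sorted(outputs.items())}
    manifest_core = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "outputs": {name: path.name for name, path in sorted(outputs.items())},
        "output_hashes": hashes,
    }
    manifest_hash = hashlib.sha256(
        json.dumps(manifest_core, sort_keys=True).encode()
    ).hexdigest()
    manifest = dict(manifest_core)
    manifest["manifest_hash"] = manifest_hash
    manifest["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
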