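"""End-to-end pipeline: simulate -> attrition -> match + weight -> outcomes
-> compare, with per-stage CSV outputs and a JSON run manifest."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, compare, ipsw, matching, outcomes, synthetic
from .cohort import CriterionConfig, cohorts_frame, run_attrition
from .io import RunManifest, write_manifest
from .matching import MatchRules
from .outcomes import CostSchedule

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "match_trial_arm", "weight_trial_arm"]


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic inputs unless paths are given."""

    registry_dir: Optional[str] = None
    trial_path: Optional[str] = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    sim: synthetic.SimConfig | None = None
    criteria: CriterionConfig = field(default_factory=CriterionConfig)
    match_rules: MatchRules = field(default_factory=MatchRules)
    match_algorithm: str = "maxcard"
    cost_schedule: CostSchedule = field(default_factory=CostSchedule)
    ipsw_p_max: float = 0.999
    t_test_method: str = "pooled"
    skip_weights: bool = False


def _drug_of_arm(arm: str) -> str:
    return arm.split("_")[0].split(":")[0]


def match_trial_arm(
    trial_df: pd.DataFrame,
    cohort_df: pd.DataFrame,
    arm: str,
    rules: MatchRules,
    algorithm: str = "maxcard",
) -> matching.MatchSet:
    """Match one trial arm against the same-drug registry cohort."""
    drug = _drug_of_arm(arm)
    participants = trial_df[trial_df["arm"] == arm]
    eyes = cohort_df[cohort_df["drug"] == drug]
    solver = (
        matching.match_max_cardinality if algorithm == "maxcard" else matching.match_greedy
    )
    return solver(participants, eyes, rules)


def weight_trial_arm(
    trial_df: pd.DataFrame,
    cohort_df: pd.DataFrame,
    arm: str,
    p_max: float = 0.999,
) -> tuple[ipsw.PropensityFit, ipsw.WeightSet, pd.DataFrame]:
    """Fit trial-membership propensity and weight the registry arm."""
    drug = _drug_of_arm(arm)
    participants = trial_df[trial_df["arm"] == arm]
    eyes = cohort_df[cohort_df["drug"] == drug].reset_index(drop=True)
    X = np.vstack(
        [ipsw.design_matrix(participants), ipsw.design_matrix(eyes)]
    )
    y = np.concatenate([np.ones(len(participants)), np.zeros(len(eyes))])
    fit = ipsw.fit_logistic(X, y, feature_names=ipsw.COVARIATES)
    weights = ipsw.att_weights(fit, eyes, p_max=p_max)
    balance = ipsw.balance_report(participants, eyes, weights)
    return fit, weights, balance


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the bundle of output frames.

    Deterministic given ``config.seed``.  Writes attrition.csv, cohorts.csv,
    pairs.csv, weights.csv, balance.csv, outcomes.csv, comparisons.csv and
    manifest.json under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- inputs ---------------------------------------------------------
    if config.registry_dir:
        from .io import load_registry

        registry = load_registry(config.registry_dir)
        truth = None
    else:
        sim = config.sim or synthetic.SimConfig(seed=config.seed)
        registry, truth = synthetic.generate_registry(sim)
    if config.trial_path:
        trial_df = pd.read_csv(config.trial_path)
    else:
        trial_df = synthetic.trial_frame(synthetic.default_trial_roster(config.seed))

    # --- attrition ------------------------------------------------------
    cohorts, attrition = run_attrition(registry, config.criteria)
    cohort_df = cohorts_frame(cohorts)
    attrition.to_frame().to_csv(out / "attrition.csv", index=False)
    cohort_df.to_csv(out / "cohorts.csv", index=False)
    logger.info("attrition table:\n%s", attrition.render())

    arms = sorted(trial_df["arm"].unique())
    pairs_frames, weight_frames, balance_frames = [], [], []
    summaries: list[outcomes.ArmSummary] = []
    contrast_inputs: dict[tuple[str, str], dict] = {}

    for arm in arms:
        drug = _drug_of_arm(arm)
        participants = trial_df[trial_df["arm"] == arm]
        eyes = cohort_df[cohort_df["drug"] == drug].reset_index(drop=True)
        if len(eyes) == 0:
            warnings.append(f"no eligible eyes for drug {drug}; arm {arm} skipped")
            continue

        # trial arm summary
        summaries.append(
            outcomes.summarize_arm(
                participants, arm=arm, drug=drug, schedule=config.cost_schedule
            )
        )
        contrast_inputs[(arm, "trial")] = {"frame": participants, "weights": None}

        # exact matching
        ms = match_trial_arm(
            trial_df, cohort_df, arm, config.match_rules, config.match_algorithm
        )
        pf = matching.pairs_frame(ms)
        pf.insert(0, "arm", arm)
        pairs_frames.append(pf)
        matched_ids = set(ms.pairs and [p.eye_id for p in ms.pairs] or [])
        eye_ids = eyes["patient_id"] + ":" + eyes["laterality"]
        matched_eyes = eyes[eye_ids.isin(matched_ids)]
        if len(matched_eyes):
            summaries.append(
                outcomes.summarize_arm(
                    matched_eyes,
                    arm=f"{drug}_prn",
                    drug=drug,
                    schedule=config.cost_schedule,
                )
            )
            summaries[-1].arm = f"{drug}_prn[exact_matching]"
            contrast_inputs[(arm, "exact_matching")] = {
                "frame": matched_eyes,
                "weights": None,
            }

        # IPSW
        if not config.skip_weights:
            fit, ws, balance = weight_trial_arm(
                trial_df, cohort_df, arm, p_max=config.ipsw_p_max
            )
            if ws.n_capped:
                warnings.append(f"{arm}: capped {ws.n_capped} propensity values")
            wf = pd.DataFrame(
                {
                    "arm": arm,
                    "patient_id": eyes["patient_id"],
                    "laterality": eyes["laterality"],
                    "weight": ws.weights,
                }
            )
            weight_frames.append(wf)
            balance = balance.copy()
            balance.insert(0, "arm", arm)
            balance_frames.append(balance)
            summaries.append(
                outcomes.summarize_arm(
                    eyes,
                    arm=f"{drug}_prn[ipsw]",
                    drug=drug,
                    weights=ws.weights,
                    schedule=config.cost_schedule,
                )
            )
            contrast_inputs[(arm, "ipsw")] = {"frame": eyes, "weights": ws.weights}

    # --- comparisons ----------------------------------------------------
    comparison_rows = []
    for arm in arms:
        for label, key_a, key_b in (
            ("exact_matching_vs_ipsw", (arm, "exact_matching"), (arm, "ipsw")),
            ("trial_vs_exact_matching", (arm, "trial"), (arm, "exact_matching")),
            ("trial_vs_ipsw", (arm, "trial"), (arm, "ipsw")),
        ):
            if key_a not in contrast_inputs or key_b not in contrast_inputs:
                continue
            va_a, w_a = _va_changes(contrast_inputs[key_a])
            va_b, w_b = _va_changes(contrast_inputs[key_b])
            if len(va_a) < 2 or len(va_b) < 2:
                continue
            res = compare.t_test_from_samples(
                va_a, va_b, method=config.t_test_method, weights_x=w_a, weights_y=w_b
            )
            comparison_rows.append(
                {
                    "arm": arm,
                    "contrast": label,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "method": res.method,
                }
            )

    # --- write bundle ---------------------------------------------------
    pairs_df = (
        pd.concat(pairs_frames, ignore_index=True) if pairs_frames else pd.DataFrame()
    )
    weights_df = (
        pd.concat(weight_frames, ignore_index=True) if weight_frames else pd.DataFrame()
    )
    balance_df = (
        pd.concat(balance_frames, ignore_index=True)
        if balance_frames
        else pd.DataFrame()
    )
    outcomes_df = outcomes.summaries_frame(summaries)
    comparisons_df = pd.DataFrame(comparison_rows)
    pairs_df.to_csv(out / "pairs.csv", index=False)
    if not config.skip_weights:
        weights_df.to_csv(out / "weights.csv", index=False)
        balance_df.to_csv(out / "balance.csv", index=False)
    outcomes_df.to_csv(out / "outcomes.csv", index=False)
    comparisons_df.to_csv(out / "comparisons.csv", index=False)
    trial_df.to_csv(out / "trial.csv", index=False)

    stage_counts = {
        "attrition_rows": len(attrition.to_frame()),
        "eligible_eyes": len(cohort_df),
        "pairs": len(pairs_df),
        "weights": len(weights_df),
        "outcome_rows": len(outcomes_df),
        "comparison_rows": len(comparisons_df),
    }
    manifest = RunManifest(
        config_hash=RunManifest.hash_config(config),
        package_version=__version__,
        seed=config.seed,
        stage_counts=stage_counts,
        warnings=warnings,
    )
    write_manifest(manifest, out / "manifest.json")
    return {
        "registry": registry,
        "ground_truth": truth,
        "trial": trial_df,
        "cohorts": cohort_df,
        "attrition": attrition,
        "pairs": pairs_df,
        "weights": weights_df,
        "balance": balance_df,
        "outcomes": outcomes_df,
        "comparisons": comparisons_df,
        "manifest": manifest,
    }


def _va_changes(entry: dict) -> tuple[np.ndarray, Optional[np.ndarray]]:
    frame, weights = entry["frame"], entry["weights"]
    year1 = pd.to_numeric(frame["year1_letters"], errors="coerce")
    mask = year1.notna().to_numpy()
    change = (year1 - frame["baseline_letters"]).to_numpy(dtype=float)[mask]
    w = None if weights is None else np.asarray(weights, dtype=float)[mask]
    return change, w
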