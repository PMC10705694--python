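"""End-to-end pipeline: simulate/load -> match -> impute -> counterfactual
PAI -> threshold sweep -> evaluation -> SHAP explanation.

Stage order and conventions:

1. cohort acquisition (simulation or CSV) and the QIDS >= 10 inclusion rule;
2. propensity-score 1:1 matching on a named covariate preset (rows missing a
   matching covariate are excluded first, with a logged count);
3. imputation within treatment class (after matching, so fill values come
   from the analysis sample);
4. counterfactual prediction and PAI scoring with the nested-CV forest;
5. PAI threshold sweep with BH-FDR;
6. model evaluation: held-out R^2 of the factual predictions, optionally a
   permutation test re-running the whole procedure;
7. global model fit and SHAP interpretation.

Every artifact is regenerable from (config, seed): two runs with the same
config produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .cohort import (
    ARM_ECT,
    ARM_KET,
    ID_COL,
    OUTCOME_COL,
    TREATMENT_COL,
    build_features,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from .evaluate import EvalResult, min_detectable_d, permutation_test, r_squared
from .explain import global_importance, shap_values
from .forest import TuningGrid, nested_cv_train
from .matching import estimate_propensity, match_1to1
from .pai import counterfactual_predict, threshold_sweep
from .preprocess import ImputationRules, compare_arms, impute
from .simulate import SimConfig, simulate_cohort, write_truth

__all__ = ["RunConfig", "RunReport", "MATCHING_PRESETS", "run_pipeline", "subgroup_run",
           "cv_r2_runner"]

logger = logging.getLogger(__name__)

#: named matching covariate sets; "full" is the primary analysis, the others
#: are the sensitivity-analysis presets
MATCHING_PRESETS: dict[str, list[str]] = {
    "full": ["qids_baseline", "age", "inpatient", "basis_psychosis"],
    "qids_only": ["qids_baseline"],
    "qids_age": ["qids_baseline", "age"],
    "qids_age_inpatient": ["qids_baseline", "age", "inpatient"],
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed is mandatory."""

    seed: int
    sim: SimConfig | None = None
    cohort_path: str | None = None
    matching_preset: str = "full"
    caliper: float | None = None
    grid: TuningGrid = field(default_factory=TuningGrid)
    outer: str = "kfold:10"
    sweep_step: float = 0.1
    permutation_B: int = 0  # 0 skips the permutation test
    explain_interactions: bool = False
    explain_top_k: int = 10
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.matching_preset not in MATCHING_PRESETS:
            raise ValueError(
                f"unknown matching preset {self.matching_preset!r}; "
                f"choose from {sorted(MATCHING_PRESETS)}"
            )
        if (self.sim is None) == (self.cohort_path is None):
            raise ValueError("exactly one cohort source (sim or cohort_path) is required")


@dataclass
class RunReport:
    summary: dict
    artifacts: dict[str, str]
    counterfactual: pd.DataFrame
    sweep: pd.DataFrame
    eval_result: EvalResult | None
    importance: pd.DataFrame
    matched_cohort: pd.DataFrame
    truth: pd.DataFrame | None = None  # simulation ground truth, if simulated


def _log_stage(name: str, t0: float, rows_in: int, rows_out: int, seed: int) -> None:
    logger.info(
        "stage=%s elapsed=%.2fs rows_in=%d rows_out=%d seed=%d",
        name, time.perf_counter() - t0, rows_in, rows_out, seed,
    )


def cv_r2_runner(
    grid: TuningGrid, outer: str = "kfold:10"
) -> Callable[[pd.DataFrame, int], float]:
    """A pipeline runner for :func:`paiselect.evaluate.permutation_test`.

    Re-runs the full counterfactual modeling procedure (tuning included) on
    the given cohort and returns the held-out R^2 of the factual
    predictions.
    """

    def _run(cohort: pd.DataFrame, seed: int) -> float:
        results, _ = counterfactual_predict(cohort, grid=grid, outer=outer, seed=seed)
        return r_squared(results[OUTCOME_COL], results["pred_actual"])

    return _run


def _acquire_cohort(config: RunConfig, out: Path | None):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=child_seed(config.seed, "simulate"))
        cohort, truth = simulate_cohort(sim)
        cohort = validate_cohort(cohort)
        if out is not None:
            write_cohort(cohort, out / "cohort.csv")
            write_truth(truth, out / "truth.json")
        return cohort, truth
    return read_cohort(config.cohort_path), None


def run_pipeline(config: RunConfig, cohort: pd.DataFrame | None = None) -> RunReport:
    """Execute all stages; returns the report (artifacts on disk if
    ``config.out_dir`` is set). ``cohort`` overrides the configured source
    (used by :func:`subgroup_run`)."""
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    t0 = time.perf_counter()
    truth = None
    if cohort is None:
        cohort, truth = _acquire_cohort(config, out)
    else:
        cohort = validate_cohort(cohort)
    _log_stage("acquire", t0, len(cohort), len(cohort), config.seed)

    # --- matching ----------------------------------------------------------
    t0 = time.perf_counter()
    covs = MATCHING_PRESETS[config.matching_preset]
    complete = cohort[covs].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("matching: %d rows excluded for missing matching covariates", n_dropped)
    pool = cohort.loc[complete].reset_index(drop=True)
    propensity = estimate_propensity(pool, covs)
    match = match_1to1(
        pool, propensity, covs, caliper=config.caliper, seed=child_seed(config.seed, "match")
    )
    matched = pool[pool[ID_COL].isin(match.matched_ids)].reset_index(drop=True)
    if out is not None:
        match.to_json(out / "match.json")
        artifacts["match"] = str(out / "match.json")
    _log_stage("match", t0, len(pool), len(matched), config.seed)

    # --- imputation + arm comparison --------------------------------------
    t0 = time.perf_counter()
    matched = impute(matched, ImputationRules())
    arm_table = compare_arms(matched)
    if out is not None:
        arm_table.to_csv(out / "arm_comparison.csv", index=False)
        artifacts["arm_comparison"] = str(out / "arm_comparison.csv")
    _log_stage("impute", t0, len(matched), len(matched), config.seed)

    # --- counterfactual PAI -------------------------------------------------
    t0 = time.perf_counter()
    results, cf_meta = counterfactual_predict(
        matched, grid=config.grid, outer=config.outer, seed=child_seed(config.seed, "cf")
    )
    if out is not None:
        results.to_csv(out / "counterfactual.csv", index=False)
        artifacts["counterfactual"] = str(out / "counterfactual.csv")
    _log_stage("counterfactual", t0, len(matched), len(results), config.seed)

    # --- threshold sweep ----------------------------------------------------
    t0 = time.perf_counter()
    sweep = threshold_sweep(results, step=config.sweep_step)
    if out is not None:
        sweep.to_csv(out / "sweep.csv", index=False)
        artifacts["sweep"] = str(out / "sweep.csv")
    _log_stage("sweep", t0, len(results), len(sweep), config.seed)

    # --- evaluation ---------------------------------------------------------
    t0 = time.perf_counter()
    r2 = r_squared(results[OUTCOME_COL], results["pred_actual"])
    eval_result: EvalResult | None = None
    if config.permutation_B > 0:
        eval_result = permutation_test(
            cv_r2_runner(config.grid, config.outer),
            matched,
            B=config.permutation_B,
            seed=child_seed(config.seed, "permtest"),
        )
        if out is not None:
            eval_result.to_json(out / "eval.json")
            artifacts["eval"] = str(out / "eval.json")
    _log_stage("evaluate", t0, len(results), len(results), config.seed)

    # --- global model + SHAP ------------------------------------------------
    t0 = time.perf_counter()
    X = build_features(matched)
    y = matched[OUTCOME_COL].to_numpy(dtype=float)
    global_model = nested_cv_train(
        X, y, grid=config.grid, seed=child_seed(config.seed, "global-model")
    )
    explanation = shap_values(global_model, X[global_model.features])
    importance = global_importance(explanation, top_k=config.explain_top_k)
    if out is not None:
        importance.to_csv(out / "shap_importance.csv", index=False)
        artifacts["shap_importance"] = str(out / "shap_importance.csv")
    _log_stage("explain", t0, len(matched), len(importance), config.seed)

    # --- summary ------------------------------------------------------------
    is_ect = results["received_arm"] == ARM_ECT
    opt_ect = results["predicted_optimal"] == ARM_ECT
    q_sig = sweep.loc[sweep["q"] < 0.05, "threshold"]
    summary = {
        "seed": config.seed,
        "matching_preset": config.matching_preset,
        "outer": cf_meta["outer"],
        "matched_n_per_arm": int(len(matched) // 2),
        "n_excluded_matching_covariates": n_dropped,
        "n_excluded_by_matching": len(match.excluded_ids),
        "fraction_predicted_optimal_ect_arm": float((opt_ect & is_ect).sum() / is_ect.sum()),
        "fraction_predicted_optimal_ket_arm": float(
            ((~opt_ect) & (~is_ect)).sum() / (~is_ect).sum()
        ),
        "fraction_received_optimal": float(results["received_optimal"].mean()),
        "r2_heldout": r2,
        "permutation_p": eval_result.permutation_p if eval_result else None,
        "first_significant_threshold": (
            float(q_sig.iloc[0]) if len(q_sig) else None
        ),
        "smd_mean_abs_before": float(np.mean(np.abs(list(match.smd_before.values())))),
        "smd_mean_abs_after": float(np.mean(np.abs(list(match.smd_after.values())))),
        "sweep": sweep.where(pd.notna(sweep), None).to_dict(orient="records"),
        "top_importance": importance.to_dict(orient="records"),
    }
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        artifacts["summary"] = str(out / "summary.json")

    return RunReport(
        summary=summary,
        artifacts=artifacts,
        counterfactual=results,
        sweep=sweep,
        eval_result=eval_result,
        importance=importance,
        matched_cohort=matched,
        truth=truth,
    )


def subgroup_run(
    config: RunConfig,
    subgroup: Callable[[pd.DataFrame], pd.Series],
    label: str = "subgroup",
) -> RunReport:
    """Run the identical pipeline on a filtered cohort.

    ``subgroup`` maps the cohort to a boolean row mask. An empty selection
    is an error; an underpowered one (fewer than ``2 * inner_k`` patients in
    an arm) proceeds with a logged minimum-detectable-effect warning.
    """
    cohort, _ = _acquire_cohort(config, None)
    mask = subgroup(cohort).astype(bool)
    if not mask.any():
        raise ValueError(f"subgroup filter {label!r} selects no patients")
    sub = cohort.loc[mask].reset_index(drop=True)

    n_ect = int((sub[TREATMENT_COL] == ARM_ECT).sum())
    n_ket = int((sub[TREATMENT_COL] == ARM_KET).sum())
    floor = 2 * config.grid.inner_k
    if min(n_ect, n_ket) < floor:
        logger.warning(
            "subgroup %s may be underpowered (arms %d/%d); minimum detectable "
            "Cohen's d at these sizes: %.3f",
            label, n_ect, n_ket, min_detectable_d(max(n_ect, 2), max(n_ket, 2)),
        )
    out_dir = config.out_dir
    sub_config = dataclasses.replace(
        config, sim=None, cohort_path="<subgroup>",
        out_dir=str(Path(out_dir) / label) if out_dir else None,
    )
    report = run_pipeline(sub_config, cohort=sub)
    n1 = report.summary["matched_n_per_arm"]
    report.summary["subgroup"] = label
    report.summary["min_detectable_d"] = min_detectable_d(max(n1, 2), max(n1, 2))
    return report
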