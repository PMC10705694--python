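"""Canonical synthetic study conditions and their recovery analyses.

These are the named experiments the package runs to validate the method on
cohorts with known ground truth; tests and the reproduction script both
call them so the conditions are defined exactly once:

- *oracle allocation*: plug the simulator's own expected outcomes in as the
  "model" — allocation must then be perfect, and the optimal-vs-non-optimal
  outcome gap must equal the simulated mean advantage up to Monte-Carlo
  error;
- *fitted recovery*: the full fitted pipeline on a strong-interaction
  cohort — directional agreement with the true optimal arm in the most
  confident (top PAI quartile) predictions, and effect-size amplification
  along the threshold sweep;
- *null calibration*: no true advantage for anyone — the FDR-adjusted sweep
  should almost never claim one;
- *permutation calibration*: outcome independent of all features — the
  permutation p-value should be roughly uniform;
- *matching improvement*: confounded naturalistic assignment — 1:1
  propensity matching must shrink covariate imbalance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .cohort import ARM_ECT, ID_COL, OUTCOME_COL, TREATMENT_COL
from .evaluate import permutation_test
from .forest import TuningGrid
from .matching import estimate_propensity, match_1to1
from .pai import compute_pai, counterfactual_predict, threshold_sweep
from .pipeline import MATCHING_PRESETS, RunConfig, cv_r2_runner, run_pipeline
from .preprocess import ImputationRules, impute
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "oracle_allocation",
    "fitted_recovery",
    "null_sweep_has_discovery",
    "permutation_calibration_p",
    "matching_improvement",
]


def _matched_with_truth(seed: int, sim: SimConfig) -> pd.DataFrame:
    cohort, truth = simulate_cohort(sim)
    covs = MATCHING_PRESETS["full"]
    pool = cohort[cohort[covs].notna().all(axis=1)].reset_index(drop=True)
    prop = estimate_propensity(pool, covs)
    match = match_1to1(pool, prop, covs, seed=child_seed(seed, "match"))
    matched = pool[pool[ID_COL].isin(match.matched_ids)].reset_index(drop=True)
    return matched.merge(truth, on=ID_COL)


def oracle_allocation(seed: int, n_per_arm: int = 235) -> dict:
    """Counterfactual scoring with the true outcome function plugged in.

    Returns the fraction of patients with positive true advantage whose
    predicted optimal arm equals the true one (must be 1.0), the observed
    optimal-vs-non-optimal mean min-QIDS difference, the simulated mean
    advantage it should match, and the Monte-Carlo standard error of the
    comparison.
    """
    sim = SimConfig.strong_interaction(seed=child_seed(seed, "sim"), n_per_arm=n_per_arm)
    merged = _matched_with_truth(seed, sim)
    is_ect = merged[TREATMENT_COL] == ARM_ECT
    pred_actual = np.where(is_ect, merged["y1_expected"], merged["y0_expected"])
    pred_flipped = np.where(is_ect, merged["y0_expected"], merged["y1_expected"])
    recs = pd.DataFrame(
        [
            compute_pai(pa, pf, arm)
            for pa, pf, arm in zip(pred_actual, pred_flipped, merged[TREATMENT_COL])
        ]
    )
    has_adv = merged["true_advantage"].to_numpy() > 0
    agreement = float(
        (recs.loc[has_adv, "predicted_optimal"].to_numpy()
         == merged.loc[has_adv, "true_optimal"].to_numpy()).mean()
    )
    opt = recs["received_optimal"].to_numpy(dtype=bool)
    y = merged[OUTCOME_COL].to_numpy(dtype=float)
    a, b = y[opt], y[~opt]
    diff = float(b.mean() - a.mean())
    mc_se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return {
        "agreement": agreement,
        "mean_difference": diff,
        "mean_true_advantage": float(merged["true_advantage"].mean()),
        "mc_se": mc_se,
        "n": int(len(merged)),
    }


def fitted_recovery(
    seed: int,
    n_per_arm: int = 235,
    grid: TuningGrid | None = None,
    outer: str = "kfold:10",
) -> dict:
    """Full fitted pipeline on a strong-interaction cohort.

    Reports directional agreement with the true optimal arm within the top
    PAI quartile, Cohen's d at threshold 0 and at the top-quartile
    threshold, and the held-out R^2.
    """
    grid = grid or TuningGrid.reduced()
    config = RunConfig(
        seed=seed,
        sim=SimConfig.strong_interaction(seed=seed, n_per_arm=n_per_arm),
        grid=grid,
        outer=outer,
    )
    rep = run_pipeline(config)
    res = rep.counterfactual.merge(rep.truth, on=ID_COL)
    q75 = float(np.quantile(res["pai"], 0.75))
    top = res[res["pai"] >= q75]
    decided = top[top["true_optimal"] != "indifferent"]
    agreement = float(
        (decided["predicted_optimal"] == decided["true_optimal"]).mean()
    )
    sweep = rep.sweep
    theta_q = np.floor(q75 / 0.1 + 1e-9) * 0.1  # top-quartile grid threshold
    row = sweep.iloc[(sweep["threshold"] - theta_q).abs().idxmin()]
    first_sig = rep.summary["first_significant_threshold"]
    return {
        "agreement_top_quartile": agreement,
        "cohens_d_threshold0": float(sweep.loc[0, "cohens_d"]),
        "cohens_d_top_quartile": float(row["cohens_d"]),
        "mean_difference_top_quartile": float(row["mean_difference"]),
        "top_quartile_threshold": float(theta_q),
        "first_significant_threshold": None if first_sig is None else float(first_sig),
        "r2_heldout": float(rep.summary["r2_heldout"]),
        "frac_advantage_ge_2": float((res["true_advantage"] >= 2).mean()),
        "n_matched_per_arm": int(rep.summary["matched_n_per_arm"]),
        "fraction_received_optimal": float(rep.summary["fraction_received_optimal"]),
    }


def null_sweep_has_discovery(
    seed: int, n_per_arm: int = 100, n_trees: int = 64
) -> bool:
    """One null replicate: does the FDR-adjusted sweep claim any advantage?"""
    sim = SimConfig.null(seed=child_seed(seed, "sim"), n_per_arm=n_per_arm)
    cohort, _ = simulate_cohort(sim)
    cohort = impute(cohort, ImputationRules())
    res, _ = counterfactual_predict(
        cohort, grid=TuningGrid.minimal(n_trees=n_trees), outer="kfold:10", seed=seed
    )
    sweep = threshold_sweep(res)
    return bool((sweep["q"] < 0.05).any())


def permutation_calibration_p(seed: int, B: int = 99) -> float:
    """Permutation p on an outcome-independent cohort (should be ~uniform)."""
    sim = SimConfig(
        n_per_arm=30,
        seed=child_seed(seed, "sim"),
        p_binary=5,
        intercept=11.0,
        prognostic_coefs={},
        prescriptive_coefs={},
        confounding_coefs={},
        noise_sd=4.0,
    )
    cohort, _ = simulate_cohort(sim)
    cohort = impute(cohort, ImputationRules())
    runner = cv_r2_runner(TuningGrid.minimal(n_trees=16), outer="kfold:3")
    return permutation_test(runner, cohort, B=B, seed=seed).permutation_p


def matching_improvement(seed: int, n_per_arm: int = 120) -> dict:
    """Mean |SMD| before/after 1:1 matching on a confounded cohort."""
    sim = SimConfig(
        n_per_arm=n_per_arm,
        seed=child_seed(seed, "sim"),
        p_binary=5,
        ect_pool_multiplier=3.0,
        basis_missing_rate=0.0,
        prescriptive_coefs={},
    )
    cohort, _ = simulate_cohort(sim)
    covs = MATCHING_PRESETS["full"]
    prop = estimate_propensity(cohort, covs)
    match = match_1to1(cohort, prop, covs, seed=seed)
    matched = cohort[cohort[ID_COL].isin(match.matched_ids)]
    sizes = matched[TREATMENT_COL].value_counts()
    return {
        "smd_before": float(np.mean(np.abs(list(match.smd_before.values())))),
        "smd_after": float(np.mean(np.abs(list(match.smd_after.values())))),
        "arms_equal": bool(sizes.nunique() == 1),
        "n_matched_per_arm": int(sizes.iloc[0]),
    }
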