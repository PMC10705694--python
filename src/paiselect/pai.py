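"""Counterfactual prediction, PAI scoring and threshold-sweep inference.

For each held-out patient the tuned forest predicts min-QIDS twice: once
with the treatment label as received and once flipped to the other arm. The
arm with the smaller predicted min-QIDS is the predicted optimal treatment
and the absolute difference between the two predictions is the patient's
Personalized Advantage Index (PAI). The sweep then compares observed
outcomes between patients who did and did not receive their predicted
optimal arm within nested subsets of increasingly confident predictions
(PAI >= threshold, thresholds 0, 0.1, ... up to the maximum PAI), with
one-sided Welch t-tests adjusted by Benjamini-Hochberg FDR.

Tie rule (documented, isolated in :func:`compute_pai`): equal predictions
mean no predicted disadvantage either way, so the received arm counts as
optimal and the PAI is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, LeaveOneOut
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed
from .cohort import (
    ARM_ECT,
    ARM_KET,
    ID_COL,
    OUTCOME_COL,
    TREATMENT_COL,
    build_features,
    flip_treatment,
)
from .forest import TuningGrid, nested_cv_train

__all__ = [
    "compute_pai",
    "counterfactual_predict",
    "one_sided_t",
    "cohens_d",
    "bh_fdr",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)


def _other_arm(arm: str) -> str:
    return ARM_KET if arm == ARM_ECT else ARM_ECT


def compute_pai(pred_actual: float, pred_flipped: float, received_arm: str) -> dict:
    """PAI fields for one patient from its two predictions."""
    if not (math.isfinite(pred_actual) and math.isfinite(pred_flipped)):
        raise ValueError("predictions must be finite")
    if pred_actual <= pred_flipped:  # tie -> received arm counts as optimal
        predicted_optimal, received_optimal = received_arm, True
    else:
        predicted_optimal, received_optimal = _other_arm(received_arm), False
    return {
        "pred_actual": float(pred_actual),
        "pred_flipped": float(pred_flipped),
        "predicted_optimal": predicted_optimal,
        "pai": abs(float(pred_actual) - float(pred_flipped)),
        "received_optimal": received_optimal,
    }


def counterfactual_predict(
    cohort: pd.DataFrame,
    grid: TuningGrid | None = None,
    outer: str = "kfold:10",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Held-out factual and counterfactual predictions for every patient.

    ``outer`` is ``"loo"`` (leave-one-out, as in the full-scale procedure)
    or ``"kfold:K"`` (its desk-scale surrogate; recorded in the returned
    metadata). Each outer training partition is tuned independently with
    :func:`paiselect.forest.nested_cv_train`; the held-out rows are then
    predicted with the recorded arm and with the label switched.

    The cohort must already be imputed. Returns ``(results, metadata)`` with
    one row per patient.
    """
    X = build_features(cohort)
    y = cohort[OUTCOME_COL].to_numpy(dtype=float)
    if X.isna().any().any():
        raise ValueError("cohort must be imputed before counterfactual prediction")

    if outer == "loo":
        splitter, outer_desc = LeaveOneOut(), "loo"
    elif outer.startswith("kfold:"):
        k = int(outer.split(":", 1)[1])
        splitter = KFold(k, shuffle=True, random_state=child_seed(seed, "outer-folds"))
        outer_desc = f"kfold:{k}"
    else:
        raise ValueError(f"unknown outer scheme {outer!r}")

    rows: list[dict] = []
    for fold_i, (tr, te) in enumerate(splitter.split(X)):
        if cohort.iloc[tr][TREATMENT_COL].nunique() < 2:
            raise ValueError("training partition contains a single treatment level")
        tuned = nested_cv_train(X.iloc[tr], y[tr], grid=grid, seed=child_seed(seed, "outer", fold_i))
        X_te = X.iloc[te]
        pred_actual = tuned.predict(X_te)
        pred_flipped = tuned.predict(flip_treatment(X_te))
        for j, row in enumerate(te):
            rec = compute_pai(pred_actual[j], pred_flipped[j], cohort.iloc[row][TREATMENT_COL])
            rec[ID_COL] = cohort.iloc[row][ID_COL]
            rec["received_arm"] = cohort.iloc[row][TREATMENT_COL]
            rec[OUTCOME_COL] = float(y[row])
            rows.append(rec)
    results = pd.DataFrame(rows)[
        [ID_COL, "received_arm", OUTCOME_COL, "pred_actual", "pred_flipped",
         "predicted_optimal", "pai", "received_optimal"]
    ]
    meta = {"outer": outer_desc, "seed": seed, "n": int(len(results))}
    return results, meta


def one_sided_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test of H1: mean(a) < mean(b).

    ``a`` holds the optimal group's outcomes (hypothesized lower). Returns
    ``(t, one-sided p)``; two groups with zero variance and equal means give
    ``(0, 0.5)`` by convention.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (-np.inf, 0.0) if a.mean() < b.mean() else (np.inf, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(t), float(p)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """|mean(b) - mean(a)| / pooled SD (n-1 weights); NaN if the pooled SD is 0."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        return float("nan")
    return float(abs(b.mean() - a.mean()) / math.sqrt(pooled_var))


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def threshold_sweep(
    results: pd.DataFrame, step: float = 0.1
) -> pd.DataFrame:
    """Optimal-vs-non-optimal outcome comparison over the PAI threshold grid.

    Thresholds run from 0 to the maximum PAI in steps of ``step``; each row
    subsets patients with ``pai >= threshold`` (so threshold 0 is the entire
    sample) and compares observed outcomes between those who received their
    predicted optimal arm and those who did not. Rows where either group has
    fewer than two patients carry undefined statistics and are excluded from
    the BH adjustment.
    """
    if len(results) == 0:
        raise ValueError("no counterfactual results")
    pai = results["pai"].to_numpy(dtype=float)
    y = results[OUTCOME_COL].to_numpy(dtype=float)
    opt = results["received_optimal"].to_numpy(dtype=bool)

    n_steps = int(math.floor(np.max(pai) / step + 1e-9)) + 1
    thresholds = step * np.arange(n_steps)

    rows = []
    for theta in thresholds:
        sel = pai >= theta - 1e-12
        a, b = y[sel & opt], y[sel & ~opt]
        row = {
            "threshold": round(float(theta), 10),
            "n_optimal": int(len(a)),
            "n_nonoptimal": int(len(b)),
            "mean_optimal": float(a.mean()) if len(a) else np.nan,
            "mean_nonoptimal": float(b.mean()) if len(b) else np.nan,
        }
        row["mean_difference"] = row["mean_nonoptimal"] - row["mean_optimal"]
        if len(a) >= 2 and len(b) >= 2:
            row["t"], row["p"] = one_sided_t(a, b)
            row["cohens_d"] = cohens_d(a, b)
            row["degenerate"] = False
        else:
            row["t"] = row["p"] = row["cohens_d"] = np.nan
            row["degenerate"] = True
        rows.append(row)
    table = pd.DataFrame(rows)

    table["q"] = np.nan
    usable = ~table["degenerate"] & table["p"].notna()
    if usable.any():
        table.loc[usable, "q"] = bh_fdr(table.loc[usable, "p"].to_numpy())
    return table
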