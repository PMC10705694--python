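"""Imputation, near-zero-variance filtering and arm comparison.

Imputation follows the clinical convention for these scales: skewed scores
(MoCA, BASIS psychosis, BASIS substance abuse) are filled with the mode,
roughly normal/uniform ones (BASIS emotional lability, relationships,
self-harm) with the mean — always within treatment class, so one arm's
distribution never leaks into the other's fill value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTINUOUS_COLS, ID_COL, TREATMENT_COL

__all__ = ["ImputationRules", "impute", "nzv_filter", "compare_arms"]


def _default_strategies() -> dict[str, str]:
    return {
        "moca": "mode",
        "basis_psychosis": "mode",
        "basis_substance_abuse": "mode",
        "basis_emotional_lability": "mean",
        "basis_relationships": "mean",
        "basis_self_harm": "mean",
    }


@dataclass
class ImputationRules:
    """Per-column fill strategy ('mode' or 'mean') and the grouping column
    defining imputation strata (default: treatment class)."""

    strategies: dict[str, str] = field(default_factory=_default_strategies)
    grouping: str = TREATMENT_COL

    def __post_init__(self) -> None:
        bad = {c: s for c, s in self.strategies.items() if s not in ("mode", "mean")}
        if bad:
            raise ValueError(f"unknown imputation strategies: {bad}")


def _fill_value(values: pd.Series, strategy: str, column: str, stratum) -> float:
    present = values.dropna()
    if present.empty:
        raise ValueError(
            f"cannot impute column {column!r}: stratum {stratum!r} has no observed values"
        )
    if strategy == "mean":
        return float(present.mean())
    # mode, ties broken by the smallest value
    counts = present.value_counts()
    top = counts[counts == counts.iloc[0]]
    return float(min(top.index))


def impute(cohort: pd.DataFrame, rules: ImputationRules | None = None) -> pd.DataFrame:
    """Fill missing values per stratum; idempotent; errors if any missing
    column lacks a declared strategy or a stratum has no donor values."""
    rules = rules or ImputationRules()
    out = cohort.copy()
    missing_cols = [c for c in out.columns if out[c].isna().any()]
    undeclared = [c for c in missing_cols if c not in rules.strategies]
    if undeclared:
        raise ValueError(f"columns with missing values but no imputation strategy: {undeclared}")
    strata = out[rules.grouping] if rules.grouping in out.columns else pd.Series(0, index=out.index)
    for col in missing_cols:
        strategy = rules.strategies[col]
        for level in pd.unique(strata):
            mask = strata == level
            hole = mask & out[col].isna()
            if hole.any():
                out.loc[hole, col] = _fill_value(out.loc[mask, col], strategy, col, level)
    return out


def nzv_filter(
    table: pd.DataFrame,
    freq_cut: float = 19.0,
    exempt: tuple[str, ...] = (TREATMENT_COL,),
) -> list[str]:
    """Near-zero-variance filter; returns retained column names.

    Drops columns with a single unique value, and columns whose ratio of the
    most frequent to the second most frequent value count exceeds
    ``freq_cut`` (default 19, the 95:5 rule; a ratio of exactly 19 is kept).
    Columns in ``exempt`` (the treatment label by default) always survive.
    """
    if table.shape[1] == 0 or table.shape[0] == 0:
        raise ValueError("empty feature table")
    retained = []
    for col in table.columns:
        if col in exempt:
            retained.append(col)
            continue
        counts = table[col].value_counts(dropna=False)
        if len(counts) < 2:
            continue
        if counts.iloc[0] / counts.iloc[1] > freq_cut:
            continue
        retained.append(col)
    return retained


def compare_arms(cohort: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Between-arm comparison of every predictor and the outcome.

    Welch t-tests for continuous variables, chi-squared with Yates
    continuity correction (2x2) for binary/categorical ones. A zero-variance
    continuous column yields an undefined (NaN) statistic rather than an
    error. Returns one row per variable: test, statistic, p, significance
    flag at ``alpha``.
    """
    arms = pd.unique(cohort[TREATMENT_COL])
    if len(arms) != 2:
        raise ValueError("compare_arms requires exactly two arms")
    a = cohort[cohort[TREATMENT_COL] == arms[0]]
    b = cohort[cohort[TREATMENT_COL] == arms[1]]

    rows = []
    for col in cohort.columns:
        if col in (ID_COL, TREATMENT_COL):
            continue
        x, y = a[col].dropna(), b[col].dropna()
        continuous = col in CONTINUOUS_COLS or cohort[col].nunique(dropna=True) > 2
        if continuous:
            test = "t"
            if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
                stat, p = np.nan, np.nan
            else:
                stat, p = stats.ttest_ind(x, y, equal_var=False)
        else:
            test = "chi2"
            tab = np.array(
                [
                    [(x == 0).sum(), (x != 0).sum()],
                    [(y == 0).sum(), (y != 0).sum()],
                ]
            )
            if (tab.sum(axis=0) == 0).any():  # one level absent everywhere
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(tab, correction=True)
        rows.append(
            {
                "variable": col,
                "test": test,
                "statistic": float(stat) if np.isfinite(stat) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    return pd.DataFrame(rows)
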