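"""Propensity-score estimation and greedy 1:1 nearest-neighbor matching.

Matching operates on the logit of the propensity score (the conventional
distance scale), greedily and without replacement: the smaller arm's
patients, in seed-randomized order, each take the nearest still-unmatched
patient from the other arm. With no caliper the smaller arm is fully
matched; a caliper is expressed in standard deviations of the logit.
Balance is reported as standardized mean differences before and after.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._seeds import rng_for
from .cohort import ARM_ECT, ID_COL, TREATMENT_COL

__all__ = ["MatchResult", "estimate_propensity", "match_1to1", "standardized_mean_differences"]


class SeparationError(RuntimeError):
    """Perfect separation in the propensity model."""


def estimate_propensity(cohort: pd.DataFrame, covariates: list[str]) -> pd.Series:
    """Fitted probabilities of receiving ECT from a maximum-likelihood
    logistic regression of treatment on ``covariates``.

    Covariates that are constant overall are dropped (intercept-only fit if
    none remain); a covariate whose per-arm ranges do not overlap separates
    the arms perfectly and raises :class:`SeparationError` naming it.
    """
    if not covariates:
        raise ValueError("at least one covariate is required")
    y = (cohort[TREATMENT_COL] == ARM_ECT).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both arms must be present")
    X = cohort[covariates].astype(float)
    if X.isna().any().any():
        raise ValueError("propensity covariates contain missing values")

    for col in covariates:
        t_vals, c_vals = X.loc[y == 1, col], X.loc[y == 0, col]
        if t_vals.min() > c_vals.max() or c_vals.min() > t_vals.max():
            raise SeparationError(f"covariate {col!r} perfectly separates the arms")

    keep = [c for c in covariates if X[c].nunique() > 1]
    design = sm.add_constant(X[keep], has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise SeparationError(f"propensity model failed to converge: {exc}") from exc
    prob = np.clip(np.asarray(fit.predict(design)), 1e-12, 1 - 1e-12)
    return pd.Series(prob, index=cohort.index, name="propensity")


def standardized_mean_differences(
    cohort: pd.DataFrame, covariates: list[str]
) -> dict[str, float]:
    """SMD per covariate: (mean_ECT - mean_KET) / sqrt((var_ECT + var_KET)/2)."""
    is_t = cohort[TREATMENT_COL] == ARM_ECT
    out: dict[str, float] = {}
    for col in covariates:
        a = cohort.loc[is_t, col].astype(float)
        b = cohort.loc[~is_t, col].astype(float)
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        out[col] = 0.0 if denom == 0 else float((a.mean() - b.mean()) / denom)
    return out


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (ECT id, KET id)
    propensity: pd.Series
    logit_scores: pd.Series
    excluded_ids: list[str]
    smd_before: dict[str, float]
    smd_after: dict[str, float]

    @property
    def matched_ids(self) -> list[str]:
        return [pid for pair in self.pairs for pid in pair]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [list(p) for p in self.pairs],
            "excluded_ids": list(self.excluded_ids),
            "smd_before": self.smd_before,
            "smd_after": self.smd_after,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def match_1to1(
    cohort: pd.DataFrame,
    propensity: pd.Series,
    covariates: list[str],
    caliper: float | None = None,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    ``caliper``, if given, is the maximum allowed logit distance in units of
    the logit's standard deviation; pairs beyond it are not formed. Raises if
    a caliper leaves zero pairs.
    """
    if propensity.isna().any():
        raise ValueError("propensity must be available for all patients")
    logit = pd.Series(
        np.log(propensity / (1.0 - propensity)), index=cohort.index, name="logit"
    )
    max_dist = np.inf if caliper is None else float(caliper) * float(logit.std(ddof=1))

    is_t = (cohort[TREATMENT_COL] == ARM_ECT).to_numpy()
    idx = cohort.index.to_numpy()
    t_idx, c_idx = idx[is_t], idx[~is_t]
    # iterate over the smaller arm so it can be fully matched
    small, large = (t_idx, c_idx) if len(t_idx) <= len(c_idx) else (c_idx, t_idx)
    order = rng_for(seed, "match-order").permutation(len(small))

    large_logit = logit.loc[large].to_numpy()
    available = np.ones(len(large), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for i in order:
        s = small[i]
        dist = np.abs(large_logit - logit.loc[s])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= max_dist:
            available[j] = False
            if cohort.loc[s, TREATMENT_COL] == ARM_ECT:
                ect_row, ket_row = s, large[j]
            else:
                ect_row, ket_row = large[j], s
            pairs.append((cohort.loc[ect_row, ID_COL], cohort.loc[ket_row, ID_COL]))
    if not pairs:
        raise ValueError("caliper too tight: no pairs formed")

    matched_ids = {pid for pair in pairs for pid in pair}
    excluded = [pid for pid in cohort[ID_COL] if pid not in matched_ids]
    matched = cohort[cohort[ID_COL].isin(matched_ids)]
    return MatchResult(
        pairs=pairs,
        propensity=propensity,
        logit_scores=logit,
        excluded_ids=excluded,
        smd_before=standardized_mean_differences(cohort, covariates),
        smd_after=standardized_mean_differences(matched, covariates),
    )
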