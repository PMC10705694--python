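"""Model performance, permutation significance and power analysis."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed, rng_for
from .cohort import OUTCOME_COL

__all__ = ["EvalResult", "r_squared", "permutation_test", "min_detectable_d"]

logger = logging.getLogger(__name__)


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Sum-of-squares coefficient of determination 1 - SS_res / SS_tot.

    Unlike a squared correlation this can be negative when predictions are
    worse than the mean.
    """
    y, yhat = np.asarray(y, dtype=float), np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("var(y) is zero; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class EvalResult:
    r2: float
    permutation_p: float
    b_used: int
    permuted_r2: list[float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "r2": self.r2,
                    "permutation_p": self.permutation_p,
                    "b_used": self.b_used,
                    "permuted_r2": self.permuted_r2,
                },
                indent=1,
            )
        )


def permutation_test(
    pipeline_runner: Callable[[pd.DataFrame, int], float],
    cohort: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> EvalResult:
    """Significance of the model's R^2 by outcome reshuffling.

    ``pipeline_runner(cohort, seed) -> r2`` must re-run the entire modeling
    procedure (tuning included). Each permutation reshuffles only the
    min-QIDS column across patients, leaving treatment and covariates
    intact. The add-one p-value ``(1 + #{r2_perm >= r2_obs}) / (B + 1)``
    never reaches 0 at finite B. A replicate whose pipeline fails is logged
    and redrawn (at most B redraws in total).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    r2_obs = float(pipeline_runner(cohort, child_seed(seed, "observed")))
    rng = rng_for(seed, "permutation-shuffles")
    permuted: list[float] = []
    failures = 0
    while len(permuted) < B:
        shuffled = cohort.copy()
        shuffled[OUTCOME_COL] = rng.permutation(shuffled[OUTCOME_COL].to_numpy())
        try:
            permuted.append(
                float(pipeline_runner(shuffled, child_seed(seed, "perm", len(permuted))))
            )
        except Exception as exc:
            failures += 1
            logger.warning("permutation replicate failed (%s); redrawing", exc)
            if failures > B:
                raise RuntimeError("too many failed permutation replicates") from exc
    p = (1 + sum(r >= r2_obs for r in permuted)) / (B + 1)
    return EvalResult(r2=r2_obs, permutation_p=float(p), b_used=B, permuted_r2=permuted)


def _power_one_sided_t(d: float, n1: int, n2: int, alpha: float) -> float:
    """Power of a one-sided two-sample t-test at effect size d."""
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(t_crit, df, nc))


def min_detectable_d(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    power: float = 0.80,
    one_sided: bool = True,
) -> float:
    """Smallest Cohen's d a two-sample t-test detects at the target power.

    Solved on the noncentral t distribution by bisection to 1e-6.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    a = alpha if one_sided else alpha / 2.0
    lo, hi = 0.0, 10.0
    while _power_one_sided_t(hi, n1, n2, a) < power:  # pragma: no cover - huge d
        hi *= 2
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2
        if _power_one_sided_t(mid, n1, n2, a) < power:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
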