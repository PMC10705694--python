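"""Random-forest outcome learner with nested cross-validation.

The learner predicts min-QIDS from pretreatment features (the treatment
label among them). Tuning mirrors the nested scheme of embedded methods:
within a training partition only, a near-zero-variance filter and a
permutation-importance ranking select features, then an inner k-fold grid
search over (mtry, splitrule, min_node_size, n_filter) picks parameters by
held-fold RMSE, and the winner is refit on the whole partition. Nothing
outside the training partition is ever touched, so held-out predictions are
leakage-free.

Conventions documented here because they matter for reproducibility:

- feature columns are canonicalized to lexicographic order before any
  fitting, making results invariant to the caller's column order;
- the treatment column is exempt from the variance filter and always forced
  into the retained feature set (counterfactual flipping is meaningless if
  the learner discards it);
- ``splitrule`` "variance" is the classic CART variance reduction
  (RandomForestRegressor), "extratrees" draws random split thresholds
  (ExtraTreesRegressor with bootstrap);
- ``min_node_size`` is the minimum samples a node needs to be split further,
  mapped to sklearn's ``min_samples_split`` (floor of 2).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import KFold

from ._seeds import child_seed
from .cohort import TREATMENT_COL
from .preprocess import nzv_filter

__all__ = [
    "RFParams",
    "TuningGrid",
    "TunedModel",
    "fit_rfr",
    "permutation_importance",
    "select_features",
    "nested_cv_train",
]

logger = logging.getLogger(__name__)

SPLITRULES = ("variance", "extratrees")


@dataclass(frozen=True)
class RFParams:
    """One random-forest configuration (1000 trees by default)."""

    n_trees: int = 1000
    mtry: int | None = None  # None -> sklearn default (all features)
    splitrule: str = "variance"
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.splitrule not in SPLITRULES:
            raise ValueError(f"splitrule must be one of {SPLITRULES}")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class TuningGrid:
    """Candidate values for the inner grid search.

    ``n_filter`` candidates: an integer retains that many top-ranked
    features, ``None`` applies the selection rule (non-zero importances
    capped at the upper 70%), and ``"all"`` skips importance ranking
    entirely. ``mtry`` / ``n_filter`` candidates of ``None`` in the default
    grid are resolved against the post-filter feature count at fit time.
    """

    mtry: Sequence[int] | None = None  # None -> {sqrt(p), p/3, p/2}
    splitrule: Sequence[str] = SPLITRULES
    min_node_size: Sequence[int] = (5, 10, 20)
    n_filter: Sequence[int | str | None] = (None,)
    inner_k: int = 10
    n_trees: int = 1000
    importance_repeats: int = 5

    @classmethod
    def reduced(cls, n_trees: int = 100) -> "TuningGrid":
        """A small two-point grid: one mtry, two node sizes, importance-based
        feature retention. Keeps the nested search intact at desk scale."""
        return cls(
            mtry=[0],  # resolved to p // 3
            splitrule=["variance"],
            min_node_size=[5, 20],
            n_filter=[None],
            n_trees=n_trees,
            importance_repeats=3,
        )

    @classmethod
    def minimal(cls, n_trees: int = 100) -> "TuningGrid":
        """A single-point grid: no inner search, no importance ranking.

        Used for desk-scale calibration runs where tuning is not the object
        of study.
        """
        return cls(
            mtry=[0],  # resolved to p // 3
            splitrule=["variance"],
            min_node_size=[5],
            n_filter=["all"],
            n_trees=n_trees,
        )

    def resolve_mtry(self, p: int) -> list[int]:
        if self.mtry is None:
            cands = {max(1, int(math.sqrt(p))), max(1, p // 3), max(1, p // 2)}
            return sorted(cands)
        return [max(1, p // 3) if m == 0 else m for m in self.mtry]


def fit_rfr(X: pd.DataFrame, y: np.ndarray, params: RFParams):
    """Fit a bootstrap ensemble of regression trees; deterministic by seed."""
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    p = X.shape[1]
    if params.mtry is not None and params.mtry > p:
        raise ValueError(f"mtry={params.mtry} exceeds feature count p={p}")
    if np.asarray(X).size and np.isnan(np.asarray(X, dtype=float)).any():
        raise ValueError("X contains missing values")
    cls = RandomForestRegressor if params.splitrule == "variance" else ExtraTreesRegressor
    model = cls(
        n_estimators=params.n_trees,
        max_features=params.mtry if params.mtry is not None else 1.0,
        min_samples_split=max(2, params.min_node_size),
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    # fit on the bare array: feature bookkeeping lives in TunedModel
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


def permutation_importance(
    model, X: pd.DataFrame, y: np.ndarray, n_repeats: int = 5, seed: int = 0
) -> pd.Series:
    """Mean MSE increase when a column is shuffled (>= over ``n_repeats``).

    A feature no tree ever splits on scores exactly 0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    res = _sk_permutation_importance(
        model,
        np.asarray(X, dtype=float),
        np.asarray(y, dtype=float),
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    return pd.Series(res.importances_mean, index=cols, name="importance")


def select_features(
    importances: pd.Series,
    fraction: float = 0.70,
    treatment_col: str = TREATMENT_COL,
    n_filter: int | None = None,
) -> list[str]:
    """Retain the top-ranked features plus (always) the treatment column.

    With ``n_filter=None`` the count is ``min(#positive importances,
    ceil(fraction * p))`` over the ``p`` candidate features (treatment
    excluded from ranking); if no importance is positive the fallback keeps
    the top ``ceil(fraction * p)`` regardless of sign. An explicit
    ``n_filter`` overrides the count. Ties are broken by column order.
    """
    ranked = importances.drop(index=treatment_col, errors="ignore")
    p = len(ranked)
    cap = math.ceil(fraction * p)
    if n_filter is None:
        k = min(int((ranked > 0).sum()), cap)
        if k == 0:
            k = cap
    else:
        k = min(int(n_filter), p)
    # stable sort keeps column order among ties
    order = ranked.iloc[np.argsort(-ranked.to_numpy(), kind="stable")]
    selected = list(order.index[:k])
    if treatment_col in importances.index:
        selected.append(treatment_col)
    return selected


@dataclass
class TunedModel:
    """A fitted forest plus everything the tuning run decided."""

    model: object
    params: RFParams
    features: list[str]
    n_filter: int | str | None
    cv_table: pd.DataFrame = field(repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(np.asarray(X[self.features], dtype=float))

    def manifest(self) -> dict:
        return {
            "n_trees": self.params.n_trees,
            "mtry": self.params.mtry,
            "splitrule": self.params.splitrule,
            "min_node_size": self.params.min_node_size,
            "n_filter": self.n_filter,
            "features": list(self.features),
        }


def _rank_features(
    X: pd.DataFrame, y: np.ndarray, grid: TuningGrid, seed: int, treatment_col: str
) -> pd.Series:
    p = X.shape[1]
    params = RFParams(
        n_trees=grid.n_trees,
        mtry=max(1, int(math.sqrt(p))),
        splitrule="variance",
        min_node_size=5,
        seed=child_seed(seed, "ranking-forest"),
    )
    model = fit_rfr(X, y, params)
    return permutation_importance(
        model, X, y, n_repeats=grid.importance_repeats, seed=child_seed(seed, "ranking-perm")
    )


def nested_cv_train(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: TuningGrid | None = None,
    seed: int = 0,
    treatment_col: str = TREATMENT_COL,
) -> TunedModel:
    """Tune and fit the outcome forest on a training partition.

    Steps, all confined to ``(X, y)``: near-zero-variance filter ->
    permutation-importance ranking -> inner k-fold grid search by RMSE ->
    refit the winning configuration on all rows. With a single grid point
    the inner search is skipped (nothing to compare).
    """
    grid = grid or TuningGrid()
    y = np.asarray(y, dtype=float)
    if len(X) < 2 * grid.inner_k and _grid_size(grid, X.shape[1]) > 1:
        raise ValueError(f"need at least {2 * grid.inner_k} rows for inner {grid.inner_k}-fold CV")

    X = X[sorted(X.columns)]  # canonical column order (see module docstring)
    kept = nzv_filter(X, exempt=(treatment_col,))
    X = X[kept]

    need_ranking = any(nf != "all" for nf in grid.n_filter)
    importances = (
        _rank_features(X, y, grid, seed, treatment_col) if need_ranking else None
    )

    feature_sets: dict[object, list[str]] = {}
    for nf in grid.n_filter:
        if nf == "all":
            feature_sets[nf] = list(X.columns)
        else:
            feature_sets[nf] = select_features(
                importances, treatment_col=treatment_col, n_filter=nf
            )

    mtry_cands = grid.resolve_mtry(X.shape[1])
    combos = list(
        itertools.product(grid.n_filter, mtry_cands, grid.splitrule, grid.min_node_size)
    )

    rows = []
    if len(combos) == 1:
        nf, mtry, rule, mns = combos[0]
        feats = feature_sets[nf]
        mtry = min(mtry, len(feats))
        best = (nf, mtry, rule, mns)
        rows.append({"n_filter": nf, "mtry": mtry, "splitrule": rule,
                     "min_node_size": mns, "rmse": np.nan})
    else:
        folds = list(
            KFold(grid.inner_k, shuffle=True, random_state=child_seed(seed, "inner-folds")).split(X)
        )
        best, best_rmse = None, np.inf
        for nf, mtry, rule, mns in combos:
            feats = feature_sets[nf]
            if mtry > len(feats):
                logger.info(
                    "grid point skipped: mtry=%d exceeds %d retained features", mtry, len(feats)
                )
                continue
            params = RFParams(
                n_trees=grid.n_trees,
                mtry=mtry,
                splitrule=rule,
                min_node_size=mns,
                seed=child_seed(seed, "inner-fit"),
            )
            sq_errs = []
            for tr, te in folds:
                m = fit_rfr(X.iloc[tr][feats], y[tr], params)
                pred = m.predict(np.asarray(X.iloc[te][feats], dtype=float))
                sq_errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
            rmse = float(np.mean(sq_errs))
            rows.append({"n_filter": nf, "mtry": mtry, "splitrule": rule,
                         "min_node_size": mns, "rmse": rmse})
            if rmse < best_rmse:
                best, best_rmse = (nf, mtry, rule, mns), rmse
        if best is None:
            raise ValueError("all grid points were skipped (mtry exceeds feature counts)")

    nf, mtry, rule, mns = best
    feats = feature_sets[nf]
    params = RFParams(
        n_trees=grid.n_trees,
        mtry=min(mtry, len(feats)),
        splitrule=rule,
        min_node_size=mns,
        seed=child_seed(seed, "final-fit"),
    )
    model = fit_rfr(X[feats], y, params)
    return TunedModel(
        model=model,
        params=params,
        features=list(feats),
        n_filter=nf,
        cv_table=pd.DataFrame(rows),
    )


def _grid_size(grid: TuningGrid, p: int) -> int:
    return (
        len(grid.resolve_mtry(p))
        * len(grid.splitrule)
        * len(grid.min_node_size)
        * len(grid.n_filter)
    )
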