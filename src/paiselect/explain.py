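"""SHAP-based interpretation of the global outcome model.

Three views, mirroring how prognostic and prescriptive information is read
off a fitted forest:

- *prognostic*: global feature importance as mean |SHAP| across patients;
- *prescriptive*: the interaction value between a predictor and the
  treatment label per patient — positive values mean the ECT label pushes
  the predicted min-QIDS up for that patient (favoring ketamine), negative
  values favor ECT;
- *individual*: waterfall decompositions running from the sample-average
  anchor (the forest's expected prediction) to one patient's prediction.

The attribution engine is the path-dependent TreeSHAP in
:mod:`paiselect.treeshap`; the baseline is the forest's cover-weighted
expected prediction, which is what makes the local-accuracy identity
``baseline + sum(phi) = prediction`` exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ID_COL, TREATMENT_COL
from .forest import TunedModel
from .treeshap import (
    ForestArrays,
    shap_interactions_arrays,
    shap_values_arrays,
    unpack_forest,
)

__all__ = [
    "Explanation",
    "shap_values",
    "shap_interactions",
    "global_importance",
    "prescriptive_profile",
    "waterfall",
]


@dataclass
class Explanation:
    """Per-patient additive attributions (QIDS points) and their baseline."""

    baseline: float
    phi: pd.DataFrame  # patients x features
    X: pd.DataFrame  # the explained feature values, same shape
    interaction: np.ndarray | None = None  # (n, p, p), rows sum to phi

    @property
    def features(self) -> list[str]:
        return list(self.phi.columns)

    def prediction(self) -> pd.Series:
        """Reconstructed predictions: baseline + row sums of phi."""
        return self.baseline + self.phi.sum(axis=1)


def _forest_and_frame(model, X: pd.DataFrame) -> tuple[ForestArrays, pd.DataFrame]:
    if isinstance(model, TunedModel):
        return unpack_forest(model.model), X[model.features]
    return unpack_forest(model), X


def shap_values(model, X: pd.DataFrame) -> Explanation:
    """Path-dependent TreeSHAP attributions for every row of ``X``.

    ``model`` is a fitted sklearn tree ensemble or a
    :class:`~paiselect.forest.TunedModel` (whose retained features are then
    selected from ``X`` automatically).
    """
    forest, Xf = _forest_and_frame(model, X)
    phi = shap_values_arrays(forest, np.asarray(Xf, dtype=float))
    return Explanation(
        baseline=forest.baseline,
        phi=pd.DataFrame(phi, index=Xf.index, columns=Xf.columns),
        X=Xf.copy(),
    )


def shap_interactions(model, X: pd.DataFrame) -> Explanation:
    """Attributions plus symmetric pairwise interaction matrices.

    ``interaction[i]`` is the p x p matrix of patient i: off-diagonal
    entries split each attribution into pairwise components, the diagonal
    holds main effects, and each row sums to the feature's SHAP value.
    """
    forest, Xf = _forest_and_frame(model, X)
    arr = np.asarray(Xf, dtype=float)
    phi = shap_values_arrays(forest, arr)
    inter = shap_interactions_arrays(forest, arr, phi)
    return Explanation(
        baseline=forest.baseline,
        phi=pd.DataFrame(phi, index=Xf.index, columns=Xf.columns),
        X=Xf.copy(),
        interaction=inter,
    )


def global_importance(explanation: Explanation, top_k: int | None = None) -> pd.DataFrame:
    """Features ranked by mean |SHAP| across patients."""
    imp = explanation.phi.abs().mean(axis=0)
    order = imp.iloc[np.argsort(-imp.to_numpy(), kind="stable")]
    table = pd.DataFrame(
        {"feature": order.index, "mean_abs_shap": order.to_numpy()}
    ).reset_index(drop=True)
    return table.head(top_k) if top_k is not None else table


def prescriptive_profile(
    explanation: Explanation,
    feature: str,
    treatment_feature: str = TREATMENT_COL,
    arms: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Treatment-interaction profile of one predictor.

    Returns per-patient rows (observed feature value, SHAP interaction with
    the treatment label, arm) plus a sign summary saying which arm the model
    favors at low versus high feature values (split at the median).
    Positive interaction values indicate an expectation of higher min-QIDS
    under the ECT label, i.e. ketamine favored.
    """
    if explanation.interaction is None:
        raise ValueError("interactions not computed; call shap_interactions first")
    feats = explanation.features
    if feature not in feats:
        raise KeyError(f"feature {feature!r} absent from the model")
    if feature == treatment_feature:
        raise ValueError("the treatment feature has no profile with itself")
    i, j = feats.index(feature), feats.index(treatment_feature)
    vals = explanation.X[feature].to_numpy(dtype=float)
    # doubled off-diagonal entry: the feature's full interaction with treatment
    inter = 2.0 * explanation.interaction[:, i, j]
    table = pd.DataFrame(
        {
            "feature_value": vals,
            "treatment_interaction_shap": inter,
            "arm": (arms.to_numpy() if arms is not None
                    else np.where(explanation.X[treatment_feature] > 0.5, "ECT", "KET")),
        },
        index=explanation.X.index,
    )
    med = float(np.median(vals))
    is_ect = table["arm"].to_numpy() == "ECT"

    def _contrast(mask: np.ndarray) -> float:
        # a patient's interaction value flips sign with their own arm, so
        # the segment's direction is the ECT-minus-KET contrast
        e = float(np.mean(inter[mask & is_ect])) if (mask & is_ect).any() else 0.0
        k = float(np.mean(inter[mask & ~is_ect])) if (mask & ~is_ect).any() else 0.0
        return e - k

    def _favored(contrast: float) -> str:
        if abs(contrast) < 1e-12:
            return "none"
        # positive: the ECT label raises predicted min-QIDS -> ketamine favored
        return "KET" if contrast > 0 else "ECT"

    c_low, c_high = _contrast(vals <= med), _contrast(vals > med)
    summary = {
        "feature": feature,
        "split_value": med,
        "favored_low": _favored(c_low),
        "favored_high": _favored(c_high),
        "mean_interaction_low": c_low,
        "mean_interaction_high": c_high,
    }
    return table, summary


def waterfall(
    explanation: Explanation, patient_id, top_k: int = 10, ids: pd.Series | None = None
) -> pd.DataFrame:
    """Ordered contribution table for one patient.

    Contributions are sorted by |SHAP| descending; everything past ``top_k``
    is aggregated as ``"other"``. The cumulative column runs from the sample
    -average baseline to the patient's prediction exactly.
    """
    index = explanation.phi.index if ids is None else pd.Index(ids)
    where = np.flatnonzero(index == patient_id)
    if len(where) == 0:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    row = explanation.phi.iloc[where[0]]
    values = explanation.X.iloc[where[0]]

    order = np.argsort(-row.abs().to_numpy(), kind="stable")
    head = order[:top_k]
    tail = order[top_k:]
    rows = [
        {"feature": row.index[k], "value": float(values.iloc[k]), "phi": float(row.iloc[k])}
        for k in head
    ]
    if len(tail):
        rows.append(
            {"feature": "other", "value": np.nan, "phi": float(row.iloc[tail].sum())}
        )
    table = pd.DataFrame(rows)
    table["cumulative"] = explanation.baseline + table["phi"].cumsum()
    table.attrs["baseline"] = explanation.baseline
    table.attrs["prediction"] = float(explanation.baseline + row.sum())
    return table
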