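"""Cohort table schema, validation and CSV round-trip.

A cohort is a plain :class:`pandas.DataFrame`, one row per patient:

======================  =======================================================
column                  meaning
======================  =======================================================
patient_id              unique identifier (string)
treatment               received arm, exactly two levels: ``"ECT"`` / ``"KET"``
qids_baseline           pretreatment QIDS, integer, inclusion requires >= 10
min_qids                outcome: minimum QIDS during acute treatment, 0-27
basis_*                 five BASIS-24 subscale scores in [0, 4], may be missing
moca                    MoCA cognitive score, integer 0-30, may be missing
age                     years
sex, inpatient          binary indicators
ind_NNN                 additional binary pretreatment indicators
======================  =======================================================

Missing values are empty cells in CSV. Simulation ground truth travels in a
sibling JSON file keyed by ``patient_id`` (see :mod:`paiselect.simulate`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARM_ECT = "ECT"
ARM_KET = "KET"
ARMS = (ARM_ECT, ARM_KET)

TREATMENT_COL = "treatment"
OUTCOME_COL = "min_qids"
ID_COL = "patient_id"

BASIS_COLS = (
    "basis_relationships",
    "basis_self_harm",
    "basis_emotional_lability",
    "basis_psychosis",
    "basis_substance_abuse",
)

#: columns every cohort must carry
MANDATORY_COLS = (ID_COL, TREATMENT_COL, "qids_baseline", OUTCOME_COL)

#: named columns treated as continuous in arm comparisons
CONTINUOUS_COLS = ("qids_baseline", OUTCOME_COL, *BASIS_COLS, "moca", "age")


class CohortSchemaError(ValueError):
    """Raised when a table violates the cohort schema."""


def predictor_columns(cohort: pd.DataFrame) -> list[str]:
    """All pretreatment predictor columns (everything except id and outcome).

    The treatment label is itself a predictor and is included.
    """
    return [c for c in cohort.columns if c not in (ID_COL, OUTCOME_COL)]


def validate_cohort(cohort: pd.DataFrame, *, apply_inclusion: bool = True) -> pd.DataFrame:
    """Validate schema, enforce the QIDS >= 10 inclusion rule, return a copy.

    Rows failing inclusion are dropped with a logged count report.
    Raises :class:`CohortSchemaError` for structural problems.
    """
    missing = [c for c in MANDATORY_COLS if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory columns: {missing}")

    levels = pd.unique(cohort[TREATMENT_COL].dropna())
    if len(levels) != 2:
        raise CohortSchemaError(
            f"treatment must take exactly two levels, found {sorted(map(str, levels))}"
        )
    unknown = set(levels) - set(ARMS)
    if unknown:
        raise CohortSchemaError(f"unknown treatment labels: {sorted(unknown)}")

    if cohort[ID_COL].duplicated().any():
        raise CohortSchemaError("duplicate patient_id values")

    out = cohort.copy()
    if apply_inclusion:
        bad = out["qids_baseline"] < 10
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning(
                "%d row%s excluded (qids_baseline < 10 inclusion rule)",
                n_bad,
                "" if n_bad == 1 else "s",
            )
            out = out.loc[~bad].reset_index(drop=True)

    oob = (out[OUTCOME_COL] < 0) | (out[OUTCOME_COL] > 27)
    if oob.any():
        raise CohortSchemaError(f"{int(oob.sum())} min_qids values outside [0, 27]")
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV; missing values become empty cells."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path, *, apply_inclusion: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype={ID_COL: str})
    return validate_cohort(df, apply_inclusion=apply_inclusion)


def build_features(cohort: pd.DataFrame, treatment_col: str = TREATMENT_COL) -> pd.DataFrame:
    """Numeric feature matrix for the learner.

    Drops id and outcome; encodes the treatment label as a 0/1 indicator
    (1 = ECT) kept under the same column name so it can be flipped for
    counterfactual prediction.
    """
    X = cohort[predictor_columns(cohort)].copy()
    X[treatment_col] = (X[treatment_col] == ARM_ECT).astype(float)
    return X.astype(float)


def flip_treatment(X: pd.DataFrame, treatment_col: str = TREATMENT_COL) -> pd.DataFrame:
    """Counterfactual copy of a feature matrix with the treatment bit toggled."""
    Xf = X.copy()
    Xf[treatment_col] = 1.0 - np.asarray(Xf[treatment_col], dtype=float)
    return Xf
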