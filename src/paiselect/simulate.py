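"""Synthetic two-arm observational cohort generator with ground truth.

Emulates a naturalistic ECT-vs-ketamine depression cohort: continuous
clinical scales (baseline QIDS, five BASIS-24 subscales, MoCA, age), binary
history/diagnosis indicators, confounded treatment assignment, and a bounded
integer outcome (min-QIDS, lower is better) built from prognostic main
effects plus treatment-by-covariate (prescriptive) interactions:

    y(t | x) = b0 + sum_j prog_j x_j + 1[t = ECT] * tau(x) + eps
    tau(x)   = c0 + sum_j presc_j x_j,   eps ~ Normal(0, noise_sd^2)

Both potential outcomes share one noise draw, are rounded half-away-from-zero
and clipped to [0, 27]. ``tau`` is the patient's true differential effect:
``true_advantage = |tau(x)|`` and the true optimal arm is the one with the
lower expected outcome.

Treatment is assigned with a logistic confounding model on covariates; arm
sizes are held exactly at ``n_per_arm`` by Gumbel top-k (softmax sampling
without replacement) on the confounding logit, so matched designs of a known
size can be simulated. MoCA and BASIS missingness is injected completely at
random at per-arm / per-column rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .cohort import ARM_ECT, ARM_KET, BASIS_COLS, ID_COL, OUTCOME_COL, TREATMENT_COL

__all__ = ["SimConfig", "simulate_cohort", "write_truth", "read_truth"]

# marginal distributions of the named clinical scales (mean, sd), chosen to
# resemble a matched ECT/ketamine TRD cohort
_SCALE_PARAMS = {
    "qids_baseline": (17.5, 3.4),
    "basis_relationships": (1.48, 0.77),
    "basis_self_harm": (1.03, 1.04),
    "basis_emotional_lability": (1.52, 0.99),
    "basis_psychosis": (0.18, 0.40),
    "basis_substance_abuse": (0.30, 0.55),
    "moca": (26.5, 2.3),
    "age": (43.0, 16.3),
}
_P_FEMALE = 0.59
_P_INPATIENT = 0.877


def _default_prognostic() -> dict[str, float]:
    """Main effects on min-QIDS: severity scales predict worse outcomes."""
    return {
        "qids_baseline": 0.55,
        "basis_self_harm": 0.9,
        "basis_psychosis": 0.8,
        "basis_emotional_lability": 0.4,
        "basis_relationships": 0.3,
        "basis_substance_abuse": 0.4,
        "age": -0.02,
        "ind_001": 1.2,
        "ind_002": 0.8,
    }


def _strong_prescriptive() -> dict[str, float]:
    """Treatment interactions giving |tau| >= 2 for over half the cohort.

    Centered so tau changes sign: tau < 0 lowers the expected min-QIDS
    under ECT, so severe baseline symptoms, self-harm and emotional
    lability favor ECT while milder presentations favor ketamine.
    """
    return {
        "_intercept": 17.22,
        "qids_baseline": -0.8,
        "basis_self_harm": -1.8,
        "basis_emotional_lability": -0.9,
    }


def _default_confounding() -> dict[str, float]:
    """Log-odds of receiving ECT: sicker, older, psychotic, inpatient."""
    return {
        "qids_baseline": 0.12,
        "inpatient": 0.9,
        "basis_psychosis": 0.9,
        "age": 0.012,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Coefficient maps are keyed by predictor column name; the reserved key
    ``"_intercept"`` contributes a constant term. ``prescriptive_coefs``
    empty (or all zero) is the null configuration: no patient has a true
    advantage under either arm.
    """

    n_per_arm: int = 235
    #: relative size of the ECT pool before matching; the naturalistic
    #: setting has many more ECT than ketamine patients, and 1:1 matching
    #: selects the best-matched subset of the larger pool
    ect_pool_multiplier: float = 1.0
    seed: int = 0
    p_binary: int = 100
    prevalence_range: tuple[float, float] = (0.01, 0.30)
    baseline_qids_mean: float = 17.5
    baseline_qids_sd: float = 3.4
    intercept: float = -1.0
    noise_sd: float = 3.0
    prognostic_coefs: dict[str, float] = field(default_factory=_default_prognostic)
    prescriptive_coefs: dict[str, float] = field(default_factory=dict)
    confounding_coefs: dict[str, float] = field(default_factory=_default_confounding)
    moca_missing_rate_by_arm: tuple[float, float] = (0.03, 0.29)  # (ECT, KET)
    basis_missing_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.ect_pool_multiplier < 1.0:
            raise ValueError("ect_pool_multiplier must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rates = (*self.moca_missing_rate_by_arm, self.basis_missing_rate, *self.prevalence_range)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates/probabilities must lie in [0, 1]")

    # -- named study conditions -------------------------------------------
    @classmethod
    def strong_interaction(cls, seed: int, n_per_arm: int = 235, **kw) -> "SimConfig":
        """Strong prescriptive structure: |tau| >= 2 QIDS points for most
        patients, outcome noise 2 — the signal-recovery study condition."""
        kw.setdefault("ect_pool_multiplier", 4.0)
        return cls(
            n_per_arm=n_per_arm,
            seed=seed,
            noise_sd=2.0,
            prescriptive_coefs=_strong_prescriptive(),
            **kw,
        )

    @classmethod
    def null(cls, seed: int, n_per_arm: int = 100, **kw) -> "SimConfig":
        """No true advantage for anyone (prescriptive effects all zero)."""
        return cls(n_per_arm=n_per_arm, seed=seed, prescriptive_coefs={}, **kw)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (QIDS is an integer scale)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _linear_term(coefs: dict[str, float], X: pd.DataFrame, what: str) -> np.ndarray:
    out = np.full(len(X), float(coefs.get("_intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "_intercept":
            continue
        if name not in X.columns:
            raise ValueError(f"{what} references undeclared predictor {name!r}")
        out += beta * X[name].to_numpy(dtype=float)
    return out


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort and its ground truth.

    Returns ``(cohort, truth)``: the cohort table (with injected missingness)
    and a truth table aligned on ``patient_id`` holding both potential
    outcomes (pre- and post-rounding), the marginal propensity of ECT, the
    true advantage ``|E[y_ECT - y_KET | x]|`` and the true optimal arm
    (``"indifferent"`` on ties). Deterministic given ``config``.
    """
    n_ket = config.n_per_arm
    n_ect = int(round(config.ect_pool_multiplier * config.n_per_arm))
    n = n_ect + n_ket
    rng = rng_for(config.seed, "covariates")

    cols: dict[str, np.ndarray] = {}
    mu_q, sd_q = config.baseline_qids_mean, config.baseline_qids_sd
    cols["qids_baseline"] = np.clip(_round_half_away(rng.normal(mu_q, sd_q, n)), 10, 27)
    for col in BASIS_COLS:
        m, s = _SCALE_PARAMS[col]
        cols[col] = np.clip(rng.normal(m, s, n), 0.0, 4.0)
    cols["moca"] = np.clip(_round_half_away(rng.normal(*_SCALE_PARAMS["moca"], n)), 0, 30)
    cols["age"] = np.clip(_round_half_away(rng.normal(*_SCALE_PARAMS["age"], n)), 18, 90)
    cols["sex"] = (rng.random(n) < _P_FEMALE).astype(float)
    cols["inpatient"] = (rng.random(n) < _P_INPATIENT).astype(float)
    lo, hi = config.prevalence_range
    prevalence = rng.uniform(lo, hi, config.p_binary)
    for j in range(config.p_binary):
        cols[f"ind_{j + 1:03d}"] = (rng.random(n) < prevalence[j]).astype(float)
    X = pd.DataFrame(cols)

    # --- treatment assignment: logistic confounding, exact arm sizes ------
    logit = _linear_term(config.confounding_coefs, X, "confounding_coefs")
    logit = logit - logit.mean() + np.log(n_ect / n_ket)
    rng_assign = rng_for(config.seed, "assignment")
    gumbel = rng_assign.gumbel(size=n)
    ect_rows = np.argsort(-(logit + gumbel))[:n_ect]
    is_ect = np.zeros(n, dtype=bool)
    is_ect[ect_rows] = True
    propensity = 1.0 / (1.0 + np.exp(-logit))

    # --- potential outcomes ----------------------------------------------
    prog = config.intercept + _linear_term(config.prognostic_coefs, X, "prognostic_coefs")
    tau = _linear_term(config.prescriptive_coefs, X, "prescriptive_coefs")
    eps = rng_for(config.seed, "noise").normal(0.0, config.noise_sd, n)
    y0_real = prog + eps  # ketamine
    y1_real = prog + tau + eps  # ECT
    y0 = np.clip(_round_half_away(y0_real), 0, 27)
    y1 = np.clip(_round_half_away(y1_real), 0, 27)

    advantage = np.abs(tau)
    optimal = np.where(tau < 0, ARM_ECT, np.where(tau > 0, ARM_KET, "indifferent"))

    ids = [f"P{i + 1:05d}" for i in range(n)]
    out_cols: dict[str, object] = {
        ID_COL: ids,
        TREATMENT_COL: np.where(is_ect, ARM_ECT, ARM_KET),
        "qids_baseline": X["qids_baseline"].astype(int),
        OUTCOME_COL: np.where(is_ect, y1, y0).astype(int),
    }
    for col in X.columns:
        if col != "qids_baseline":
            out_cols[col] = X[col].to_numpy()
    cohort = pd.DataFrame(out_cols)

    # --- MCAR missingness --------------------------------------------------
    rng_miss = rng_for(config.seed, "missingness")
    rate_ect, rate_ket = config.moca_missing_rate_by_arm
    moca_rate = np.where(is_ect, rate_ect, rate_ket)
    cohort.loc[rng_miss.random(n) < moca_rate, "moca"] = np.nan
    for col in BASIS_COLS:
        cohort.loc[rng_miss.random(n) < config.basis_missing_rate, col] = np.nan

    truth = pd.DataFrame(
        {
            ID_COL: ids,
            "y0_expected": prog,  # noise-free expected potential outcomes
            "y1_expected": prog + tau,
            "y0_real": y0_real,
            "y1_real": y1_real,
            "y0": y0.astype(int),
            "y1": y1.astype(int),
            "propensity": propensity,
            "true_advantage": advantage,
            "true_optimal": optimal,
        }
    )
    return cohort, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Ground truth to JSON keyed by patient_id."""
    records = truth.set_index(ID_COL).to_dict(orient="index")
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> pd.DataFrame:
    records = json.loads(Path(path).read_text())
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = ID_COL
    return df.reset_index()
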