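import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True)
settings.load_profile("fixed")

from paiselect import (
    ImputationRules,
    SimConfig,
    impute,
    simulate_cohort,
)

warnings.filterwarnings("ignore", message="DataFrame is highly fragmented")


@pytest.fixture(scope="session")
def small_strong():
    """A small strong-interaction cohort with truth, imputed, for reuse."""
    cfg = SimConfig.strong_interaction(seed=11, n_per_arm=80, p_binary=20)
    cohort, truth = simulate_cohort(cfg)
    return impute(cohort, ImputationRules()), truth


@pytest.fixture
def rng():
    return np.random.default_rng(202409)


@pytest.fixture
def toy_counterfactual():
    """Hand-built 8-patient counterfactual table with known group means."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "received_arm": ["ECT"] * 4 + ["KET"] * 4,
            "min_qids": [8.0, 9.0, 14.0, 15.0, 7.0, 10.0, 13.0, 16.0],
            "pred_actual": [10, 10, 12, 12, 9, 9, 13, 13.0],
            "pred_flipped": [11, 10.5, 11.8, 13, 9.2, 8.5, 12.3, 14.1],
            "pai": [1.0, 0.5, 0.2, 1.0, 0.2, 0.5, 0.7, 1.1],
            "received_optimal": [True, True, False, True, True, False, False, True],
        }
    )
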