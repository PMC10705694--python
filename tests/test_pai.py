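"""PAI scoring, counterfactual prediction and threshold-sweep inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paiselect import (
    ImputationRules,
    SimConfig,
    TuningGrid,
    bh_fdr,
    build_features,
    cohens_d,
    compute_pai,
    counterfactual_predict,
    flip_treatment,
    impute,
    one_sided_t,
    simulate_cohort,
    threshold_sweep,
)

from oracles import bh_stepup, pooled_cohens_d, welch_t_one_sided


class TestComputePAI:
    def test_lower_actual_prediction_means_received_optimal(self):
        rec = compute_pai(10.0, 13.0, "KET")
        assert rec == {
            "pred_actual": 10.0,
            "pred_flipped": 13.0,
            "predicted_optimal": "KET",
            "pai": 3.0,
            "received_optimal": True,
        }

    def test_higher_actual_prediction_means_received_non_optimal(self):
        rec = compute_pai(14.0, 11.0, "ECT")
        assert rec["predicted_optimal"] == "KET"
        assert rec["pai"] == 3.0
        assert rec["received_optimal"] is False

    def test_tie_counts_as_received_optimal_with_zero_pai(self):
        rec = compute_pai(12.0, 12.0, "ECT")
        assert rec["pai"] == 0.0
        assert rec["predicted_optimal"] == "ECT"
        assert rec["received_optimal"] is True

    def test_non_finite_predictions_rejected(self):
        with pytest.raises(ValueError):
            compute_pai(float("nan"), 1.0, "ECT")


class TestOneSidedT:
    def test_matches_closed_form_welch(self):
        t, p = one_sided_t([1.0, 2, 3], [4.0, 5, 6])
        t_ref, p_ref = welch_t_one_sided([1.0, 2, 3], [4.0, 5, 6])
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0107, abs=5e-4)

    def test_identical_groups_give_half(self):
        t, p = one_sided_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 0.5)

    def test_large_separation_gives_tiny_p(self, rng):
        a = rng.normal(-10, 1, 50)
        b = rng.normal(0, 1, 50)
        _, p = one_sided_t(a, b)
        assert p < 1e-10


class TestCohensD:
    def test_unit_pooled_sd_example(self):
        assert cohens_d([1.0, 2, 3], [4.0, 5, 6]) == pytest.approx(3.0, abs=1e-12)

    def test_identical_groups_give_zero(self):
        assert cohens_d([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_shift_in_sd_units_recovers_the_shift(self, rng):
        a = rng.normal(0, 1, 10_000)
        b = a + 0.75 * a.std(ddof=1)
        assert cohens_d(a, b) == pytest.approx(0.75, abs=1e-6)

    def test_matches_pooled_formula_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            assert cohens_d(a, b) == pytest.approx(pooled_cohens_d(a, b), abs=1e-12)

    def test_zero_pooled_sd_is_undefined(self):
        assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestBHFDR:
    def test_textbook_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=120, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=8)
    )
    def test_matches_stepup_definition(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_stepup(pvals), atol=1e-12)
        q = bh_fdr(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0).all()


class TestThresholdSweep:
    def test_grid_runs_to_max_pai_in_steps_of_one_tenth(self, toy_counterfactual):
        tc = toy_counterfactual.copy()
        tc.loc[7, "pai"] = 1.43
        sweep = threshold_sweep(tc)
        assert np.allclose(sweep["threshold"], np.arange(0, 1.5, 0.1))

    def test_hand_built_fixture_reproduces_group_means(self, toy_counterfactual):
        sweep = threshold_sweep(toy_counterfactual)
        y = toy_counterfactual["min_qids"].to_numpy()
        opt = toy_counterfactual["received_optimal"].to_numpy()
        pai = toy_counterfactual["pai"].to_numpy()
        for _, row in sweep.iterrows():
            sel = pai >= row["threshold"] - 1e-12
            assert row["n_optimal"] == (sel & opt).sum()
            assert row["n_nonoptimal"] == (sel & ~opt).sum()
            if row["n_optimal"]:
                assert row["mean_optimal"] == pytest.approx(y[sel & opt].mean())
            if row["n_nonoptimal"]:
                assert row["mean_nonoptimal"] == pytest.approx(y[sel & ~opt].mean())

    def test_subset_sizes_never_increase_with_threshold(self, toy_counterfactual):
        sweep = threshold_sweep(toy_counterfactual)
        sizes = (sweep["n_optimal"] + sweep["n_nonoptimal"]).to_numpy()
        assert (np.diff(sizes) <= 0).all()
        assert sizes[0] == len(toy_counterfactual)  # threshold 0 = entire sample

    def test_q_is_at_least_p_and_degenerate_rows_are_excluded(self, toy_counterfactual):
        sweep = threshold_sweep(toy_counterfactual)
        ok = ~sweep["degenerate"]
        assert (sweep.loc[ok, "q"] >= sweep.loc[ok, "p"] - 1e-12).all()
        assert sweep.loc[~ok, "q"].isna().all()

    def test_all_zero_pai_is_single_degenerate_row(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "received_arm": ["ECT", "KET", "ECT"],
                "min_qids": [5.0, 6.0, 7.0],
                "pred_actual": [1.0, 1.0, 1.0],
                "pred_flipped": [1.0, 1.0, 1.0],
                "pai": [0.0, 0.0, 0.0],
                "received_optimal": [True, True, True],
            }
        )
        sweep = threshold_sweep(df)
        assert len(sweep) == 1
        assert bool(sweep.loc[0, "degenerate"])
        assert sweep.loc[0, "n_optimal"] == 3


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = SimConfig.strong_interaction(
        seed=21, n_per_arm=30, p_binary=5, ect_pool_multiplier=1.0
    )
    cohort, _ = simulate_cohort(cfg)
    return impute(cohort, ImputationRules())


class TestCounterfactualPredict:
    def test_double_flip_returns_original_matrix(self, tiny_cohort):
        X = build_features(tiny_cohort)
        pd.testing.assert_frame_equal(flip_treatment(flip_treatment(X)), X)

    def test_constant_outcome_gives_zero_pai_everywhere(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort["min_qids"] = 9
        res, _ = counterfactual_predict(
            cohort, grid=TuningGrid.minimal(n_trees=10), outer="kfold:3", seed=0
        )
        assert np.allclose(res["pai"], 0.0)
        assert res["received_optimal"].all()

    def test_every_patient_predicted_once_with_metadata(self, tiny_cohort):
        res, meta = counterfactual_predict(
            tiny_cohort, grid=TuningGrid.minimal(n_trees=10), outer="kfold:3", seed=1
        )
        assert sorted(res["patient_id"]) == sorted(tiny_cohort["patient_id"])
        assert meta["outer"] == "kfold:3"
        assert (res["pai"] >= 0).all()

    def test_corrupting_a_heldout_outcome_leaves_its_prediction_unchanged(
        self, tiny_cohort
    ):
        """Models never see their held-out fold: poisoning one patient's
        outcome cannot change that patient's own prediction."""
        grid = TuningGrid.minimal(n_trees=10)
        base, _ = counterfactual_predict(tiny_cohort, grid=grid, outer="kfold:3", seed=5)
        poisoned = tiny_cohort.copy()
        pid = poisoned.loc[3, "patient_id"]
        poisoned.loc[3, "min_qids"] = 0 if poisoned.loc[3, "min_qids"] > 0 else 27
        after, _ = counterfactual_predict(poisoned, grid=grid, outer="kfold:3", seed=5)
        b = base.set_index("patient_id").loc[pid]
        a = after.set_index("patient_id").loc[pid]
        assert a["pred_actual"] == b["pred_actual"]
        assert a["pred_flipped"] == b["pred_flipped"]

    def test_single_treatment_level_training_partition_is_an_error(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort["treatment"] = np.where(np.arange(len(cohort)) == 0, "KET", "ECT")
        with pytest.raises(ValueError, match="single treatment level"):
            counterfactual_predict(
                cohort, grid=TuningGrid.minimal(n_trees=5), outer="kfold:2", seed=0
            )


def test_oracle_plug_in_recovers_true_optimal_assignment():
    """Predicting with the simulator's own expected outcomes must label
    every patient with positive advantage by their true optimal arm."""
    cfg = SimConfig.strong_interaction(seed=33, n_per_arm=60, p_binary=5)
    cohort, truth = simulate_cohort(cfg)
    merged = cohort.merge(truth, on="patient_id")
    is_ect = merged["treatment"] == "ECT"
    pred_actual = np.where(is_ect, merged["y1_expected"], merged["y0_expected"])
    pred_flipped = np.where(is_ect, merged["y0_expected"], merged["y1_expected"])
    records = [
        compute_pai(pa, pf, arm)
        for pa, pf, arm in zip(pred_actual, pred_flipped, merged["treatment"])
    ]
    predicted_optimal = np.array([r["predicted_optimal"] for r in records])
    has_advantage = merged["true_advantage"] > 0
    assert (predicted_optimal[has_advantage] == merged.loc[has_advantage, "true_optimal"]).all()
    pai = np.array([r["pai"] for r in records])
    assert np.allclose(pai, merged["true_advantage"])
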