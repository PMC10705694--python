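"""TreeSHAP attributions: exactness against exhaustive Shapley enumeration,
additivity identities, and the interpretation helpers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from paiselect import (
    ImputationRules,
    RFParams,
    SimConfig,
    fit_rfr,
    global_importance,
    impute,
    prescriptive_profile,
    shap_interactions,
    shap_values,
    simulate_cohort,
    waterfall,
)
from paiselect.cohort import build_features

from oracles import exact_interactions, exact_shap


def _fit_small_forest(seed, n=60, p=4, depth=3, trees=4, interaction=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p)
    if interaction:
        y = y + 1.5 * X[:, 0] * X[:, 1]
    y = y + 0.1 * rng.normal(size=n)
    model = RandomForestRegressor(
        n_estimators=trees, max_depth=depth, random_state=seed
    ).fit(X, y)
    return model, rng.normal(size=(4, p))


class TestShapValues:
    def test_single_feature_model_attributes_everything_to_it(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 1))
        y = 2.0 * X[:, 0]
        model = RandomForestRegressor(n_estimators=5, random_state=0).fit(X, y)
        expl = shap_values(model, pd.DataFrame(X, columns=["x"]))
        pred = model.predict(X)
        assert np.allclose(expl.phi["x"], pred - expl.baseline, atol=1e-10)

    def test_matches_exhaustive_shapley_enumeration(self):
        for seed in range(4):
            model, Xt = _fit_small_forest(seed, p=3 + seed % 3)
            expl = shap_values(model, pd.DataFrame(Xt))
            for i in range(len(Xt)):
                ref = exact_shap(model, Xt[i], Xt.shape[1])
                assert np.allclose(expl.phi.iloc[i], ref, atol=1e-6)

    def test_local_accuracy_on_a_simulated_cohort_model(self, small_strong):
        cohort, _ = small_strong
        X = build_features(cohort)
        y = cohort["min_qids"].to_numpy(dtype=float)
        model = fit_rfr(X, y, RFParams(n_trees=40, mtry=8, seed=0))
        expl = shap_values(model, X)
        pred = model.predict(np.asarray(X, dtype=float))
        assert np.max(np.abs(expl.baseline + expl.phi.sum(axis=1) - pred)) < 1e-6

    def test_non_tree_model_rejected(self):
        model = LinearRegression().fit([[0.0], [1.0]], [0.0, 1.0])
        with pytest.raises(TypeError):
            shap_values(model, pd.DataFrame({"x": [0.5]}))


class TestShapInteractions:
    def test_matches_exhaustive_pairwise_enumeration(self):
        for seed in range(2):
            model, Xt = _fit_small_forest(seed, p=4, interaction=True)
            expl = shap_interactions(model, pd.DataFrame(Xt))
            for i in range(3):
                ref = exact_interactions(model, Xt[i], 4)
                assert np.allclose(expl.interaction[i], ref, atol=1e-6)

    def test_purely_additive_ensemble_has_zero_off_diagonals(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 2))
        t1 = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X[:, :1], 2 * X[:, 0])
        t2 = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X[:, 1:], -X[:, 1])

        class TwoTree:
            estimators_ = None
            n_features_in_ = 2

        # additive forest: tree A splits only on x0, tree B only on x1
        tA = DecisionTreeRegressor(max_depth=3, random_state=0).fit(
            np.c_[X[:, 0], np.zeros(100)], 2 * X[:, 0]
        )
        tB = DecisionTreeRegressor(max_depth=3, random_state=0).fit(
            np.c_[np.zeros(100), X[:, 1]], -X[:, 1]
        )
        m = TwoTree()
        m.estimators_ = [tA, tB]
        expl = shap_interactions(m, pd.DataFrame(rng.normal(size=(5, 2))))
        off = expl.interaction[:, 0, 1]
        assert np.max(np.abs(off)) < 1e-6

    def test_rows_sum_to_phi_and_matrices_symmetric(self):
        model, Xt = _fit_small_forest(7, p=5, interaction=True)
        expl = shap_interactions(model, pd.DataFrame(Xt))
        assert np.allclose(expl.interaction.sum(axis=2), expl.phi.to_numpy(), atol=1e-6)
        assert np.allclose(
            expl.interaction, expl.interaction.transpose(0, 2, 1), atol=1e-6
        )


class TestGlobalImportance:
    def test_unused_feature_has_zero_importance_and_ranks_last(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"signal": rng.normal(size=100), "dead": np.zeros(100)}
        )
        y = 3 * X["signal"].to_numpy()
        model = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
        table = global_importance(shap_values(model, X))
        assert table.iloc[-1]["feature"] == "dead"
        assert table.iloc[-1]["mean_abs_shap"] == 0.0

    def test_dominant_prognostic_feature_ranks_first(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            X = pd.DataFrame(rng.normal(size=(120, 5)), columns=list("abcde"))
            y = 5 * X["c"].to_numpy() + 0.3 * rng.normal(size=120)
            model = RandomForestRegressor(n_estimators=30, random_state=s).fit(X, y)
            table = global_importance(shap_values(model, X))
            hits += table.iloc[0]["feature"] == "c"
        assert hits >= 4

    def test_ranking_invariant_to_patient_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X["a"].to_numpy() - X["b"].to_numpy()
        model = RandomForestRegressor(n_estimators=15, random_state=0).fit(X, y)
        t1 = global_importance(shap_values(model, X))
        t2 = global_importance(shap_values(model, X.iloc[::-1]))
        pd.testing.assert_frame_equal(t1, t2)


@pytest.fixture(scope="module")
def cohort_explanation():
    cfg = SimConfig.strong_interaction(
        seed=8, n_per_arm=60, p_binary=4, ect_pool_multiplier=1.0
    )
    cohort, truth = simulate_cohort(cfg)
    cohort = impute(cohort, ImputationRules())
    X = build_features(cohort)
    y = cohort["min_qids"].to_numpy(dtype=float)
    model = fit_rfr(X, y, RFParams(n_trees=60, mtry=5, seed=0))
    return shap_interactions(model, X), cohort


class TestPrescriptiveProfile:
    def test_planted_interaction_direction_is_recovered(self, cohort_explanation):
        """The simulator plants an ECT advantage growing with baseline QIDS
        (centered): the treatment-interaction profile must favor ECT at high
        and KET at low values."""
        expl, cohort = cohort_explanation
        table, summary = prescriptive_profile(expl, "qids_baseline")
        assert summary["favored_high"] == "ECT"
        assert summary["favored_low"] == "KET"
        assert summary["mean_interaction_high"] < summary["mean_interaction_low"]

    def test_null_interaction_is_weaker_than_planted_one(self, cohort_explanation):
        expl, cohort = cohort_explanation
        null_cfg = SimConfig.null(seed=8, n_per_arm=60, p_binary=4, noise_sd=2.0)
        ncohort, _ = simulate_cohort(null_cfg)
        ncohort = impute(ncohort, ImputationRules())
        Xn = build_features(ncohort)
        yn = ncohort["min_qids"].to_numpy(dtype=float)
        nmodel = fit_rfr(Xn, yn, RFParams(n_trees=60, mtry=5, seed=0))
        nexpl = shap_interactions(nmodel, Xn)
        planted = np.abs(prescriptive_profile(expl, "qids_baseline")[0][
            "treatment_interaction_shap"]).mean()
        null = np.abs(prescriptive_profile(nexpl, "qids_baseline")[0][
            "treatment_interaction_shap"]).mean()
        assert planted > null

    def test_treatment_profile_with_itself_is_excluded(self, cohort_explanation):
        expl, _ = cohort_explanation
        with pytest.raises(ValueError):
            prescriptive_profile(expl, "treatment")

    def test_absent_feature_is_an_error(self, cohort_explanation):
        expl, _ = cohort_explanation
        with pytest.raises(KeyError):
            prescriptive_profile(expl, "not_a_feature")


@pytest.fixture(scope="module")
def explanation():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(30, 6)), columns=[f"f{j}" for j in range(6)])
    y = X.to_numpy() @ rng.normal(size=6)
    model = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
    expl = shap_values(model, X)
    expl.phi.index = [f"P{i}" for i in range(30)]
    expl.X.index = expl.phi.index
    return expl, model, X


class TestWaterfall:
    def test_full_depth_cumulative_ends_at_prediction(self, explanation):
        expl, model, X = explanation
        table = waterfall(expl, "P4", top_k=6)
        assert table["cumulative"].iloc[-1] == pytest.approx(
            model.predict(np.asarray(X))[4], abs=1e-6
        )

    def test_top_k_zero_is_single_other_bar(self, explanation):
        expl, model, X = explanation
        table = waterfall(expl, "P0", top_k=0)
        assert list(table["feature"]) == ["other"]
        assert table["phi"].iloc[0] == pytest.approx(
            model.predict(np.asarray(X))[0] - expl.baseline, abs=1e-6
        )

    def test_ordering_is_by_absolute_contribution(self, explanation):
        expl, _, _ = explanation
        table = waterfall(expl, "P7", top_k=6)
        mags = table["phi"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()

    def test_unknown_patient_is_an_error(self, explanation):
        expl, _, _ = explanation
        with pytest.raises(KeyError):
            waterfall(expl, "nobody")
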