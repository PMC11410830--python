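import numpy as np
import pandas as pd
import pytest

from gcfpool import (
    MODEL_SPECS,
    build_feature_table,
    dissimilarity_table,
    distance_matrix_from_effects,
    effects_table,
    fit_hierarchy,
    null_predictions,
    permutation_importance,
    predictions_frame,
)


@pytest.fixture(scope="module")
def small_fit(pool, noisy_small):
    """Feature table built from the small noisy experiment."""
    _, design, responses = noisy_small
    effects = effects_table(design, responses, B=300, seed=0)
    preds = predictions_frame(null_predictions(design, responses, K=100, seed=0))
    single = effects[effects["treatment_id"].str.startswith("single_")].copy()
    single["factor"] = single["treatment_id"].str.removeprefix("single_")
    matrix = single.pivot(index="factor", columns="response", values="effect")
    di = dissimilarity_table(design, distance_matrix_from_effects(matrix))
    features = build_feature_table(design, responses, effects, preds, di, pool.factors)
    return design, responses, effects, preds, di, features


def synthetic_features(n=200, seed=0, beta_n=0.0, beta_di=0.0, noise=1.0):
    """Hand-built feature rows with a controllable generative model."""
    rng = np.random.default_rng(seed)
    null_add = rng.normal(0, 2, n)
    features = pd.DataFrame(
        {
            "response": "r",
            "null_additive": null_add,
            "null_multiplicative": null_add + rng.normal(0, 0.1, n),
            "null_dominative": 0.5 * null_add + rng.normal(0, 0.5, n),
            "n_factors": rng.choice([2, 5, 8], n).astype(float),
            "di_norm": rng.uniform(0, 1, n),
        }
    )
    features["y"] = (
        features["null_additive"]
        + beta_n * features["n_factors"]
        + beta_di * features["di_norm"]
        + rng.normal(0, noise, n)
    )
    return features


class TestFeatureTable:
    def test_row_counts_match_design_units(self, small_fit):
        design, _, _, _, _, features = small_fit
        units = design.loc[design["kind"].isin(["single", "multi"]), "n_replicates"].sum()
        assert (features.groupby("response").size() == units).all()

    def test_composition_sums_to_level(self, small_fit, pool):
        _, _, _, _, _, features = small_fit
        comp = features[[f"comp_{f}" for f in pool.factors]].sum(axis=1)
        assert (comp == features["n_factors"]).all()

    def test_null_columns_match_predictions_verbatim(self, small_fit):
        # join-integrity: multi rows carry the null_models outputs unchanged
        _, _, _, preds, _, features = small_fit
        wide = preds.pivot_table(
            index=["treatment_id", "response"], columns="model", values="pred_mean"
        )
        multi = features[features["n_factors"] > 1].drop_duplicates(
            ["treatment_id", "response"]
        )
        for _, row in multi.head(20).iterrows():
            expected = wide.loc[(row["treatment_id"], row["response"])]
            assert row["null_additive"] == expected["additive"]
            assert row["null_multiplicative"] == expected["multiplicative"]
            assert row["null_dominative"] == expected["dominative"]

    def test_singles_get_level_one_and_zero_di(self, small_fit):
        _, _, _, _, _, features = small_fit
        singles = features[features["treatment_id"].str.startswith("single_")]
        assert (singles["n_factors"] == 1).all()
        assert (singles["di_norm"] == 0).all()

    def test_orphan_predictions_raise(self, small_fit, pool):
        design, responses, effects, preds, di, _ = small_fit
        rogue = preds.copy()
        rogue.loc[rogue.index[0], "treatment_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            build_feature_table(design, responses, effects, rogue, di, pool.factors)


class TestGlmHierarchy:
    def test_perfect_baseline_r2_one(self):
        features = synthetic_features(noise=0.0)
        features["y"] = features["null_additive"]
        models = fit_hierarchy(features, backend="glm")["r"].models
        assert models[1]["r2"] == pytest.approx(1.0, abs=1e-10)
        for mid in (4, 5, 6):
            assert models[mid]["delta_r2"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_number_of_factors_term(self):
        features = synthetic_features(seed=1, beta_n=1.0, noise=0.5)
        models = fit_hierarchy(features, backend="glm")["r"].models
        assert models[4]["delta_r2"] > 0.1
        assert models[4]["aic"] < models[1]["aic"]
        assert models[4]["anova_p"] < 1e-6

    def test_recovers_dissimilarity_term(self):
        features = synthetic_features(seed=2, beta_di=3.0, noise=0.5)
        models = fit_hierarchy(features, backend="glm")["r"].models
        assert models[5]["delta_r2"] > 0.1
        assert models[5]["aic"] < models[1]["aic"]

    def test_r2_nondecreasing_along_nested_chains(self, small_fit):
        _, _, _, _, _, features = small_fit
        for rep in fit_hierarchy(features, backend="glm").values():
            r2 = {mid: rep.models[mid]["r2"] for mid in MODEL_SPECS}
            for chain in [(1, 4, 6, 7), (1, 5, 6, 7)]:
                for lo, hi in zip(chain, chain[1:]):
                    assert r2[hi] >= r2[lo] - 1e-10

    def test_aliased_composition_dropped_with_warning(self, small_fit):
        _, _, _, _, _, features = small_fit
        with pytest.warns(RuntimeWarning, match="aliased"):
            fit_hierarchy(features, backend="glm")

    def test_min_rows_enforced(self):
        features = synthetic_features(n=10)
        with pytest.raises(ValueError, match="min_rows"):
            fit_hierarchy(features, backend="glm", min_rows=30)


class TestForestHierarchy:
    def test_deterministic_under_seed_and_reports_oob(self):
        features = synthetic_features(seed=3, beta_n=1.0, noise=0.5)
        a = fit_hierarchy(features, backend="forest", seed=5, n_estimators=50)["r"].models
        b = fit_hierarchy(features, backend="forest", seed=5, n_estimators=50)["r"].models
        assert a[6]["r2"] == b[6]["r2"]
        assert a[7]["r2"] >= a[1]["r2"] - 0.1  # composition-rich model not worse

    def test_backends_rank_contributions_identically(self):
        # linear world with a strong number-of-factors term: both backends
        # should attribute more increment to Model 4 than Model 5
        features = synthetic_features(seed=4, beta_n=2.0, noise=0.5)
        glm = fit_hierarchy(features, backend="glm")["r"].models
        rf = fit_hierarchy(features, backend="forest", seed=1, n_estimators=80)["r"].models
        assert glm[4]["delta_r2"] > glm[5]["delta_r2"]
        assert rf[4]["delta_r2"] > rf[5]["delta_r2"]


class TestPermutationImportance:
    def test_response_equal_to_predictor_maximizes_importance(self):
        features = synthetic_features(seed=5, noise=0.0)
        features["y"] = features["di_norm"]
        imp = permutation_importance(
            features, features["y"].to_numpy(),
            ["null_additive", "n_factors", "di_norm"],
            n_perm=30, seed=0, n_estimators=50,
        )
        best = imp.loc[imp["importance"].idxmax(), "predictor"]
        assert best == "di_norm"
        assert imp.loc[imp["predictor"] == "di_norm", "p_raw"].iloc[0] <= 1 / 31 + 1e-12

    def test_deterministic_under_seed(self):
        features = synthetic_features(seed=6, beta_n=1.0)
        args = (features, features["y"].to_numpy(), ["null_additive", "n_factors"])
        a = permutation_importance(*args, n_perm=10, seed=3, n_estimators=30)
        b = permutation_importance(*args, n_perm=10, seed=3, n_estimators=30)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_pvalues_under_global_null(self):
        # y independent of every predictor: Altmann p-values are uniform
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(30):
            features = pd.DataFrame(
                rng.normal(size=(60, 3)), columns=["null_additive", "n_factors", "di_norm"]
            )
            features["response"] = "r"
            y = rng.normal(size=60)
            imp = permutation_importance(
                features, y, ["null_additive", "n_factors", "di_norm"],
                n_perm=19, seed=rep, n_estimators=20, n_repeats=2,
            )
            pvals.extend(imp["p_raw"].tolist())
        pvals = np.asarray(pvals)
        assert 0.35 < pvals.mean() < 0.65
        assert (pvals < 0.25).mean() < 0.45  # no pile-up at small p
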