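import numpy as np
import pandas as pd
import pytest

from gcfpool import (
    classify_interaction,
    deviation_group_tests,
    dn_vs_di_correlation,
    interaction_calls,
    rescaled_deviation,
    select_best_null,
)
from gcfpool.nullmodels import NullPrediction


def make_prediction(draws, model="additive", treatment="t1", response="r1"):
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return NullPrediction(
        model=model, draws=draws, mean=float(draws.mean()),
        ci_low=float(lo), ci_high=float(hi),
        treatment_id=treatment, response=response,
    )


class TestRescaledDeviation:
    def test_zero_at_prediction_mean(self):
        pred = make_prediction([1.0, 2.0, 3.0])
        assert rescaled_deviation(2.0, pred) == 0.0

    def test_definitional_two_sd(self):
        draws = np.array([-1.0, 1.0] * 50)  # mean 0, sd ~1
        pred = make_prediction(draws)
        sd = draws.std(ddof=1)
        assert rescaled_deviation(2.0 * sd, pred) == pytest.approx(2.0)

    def test_moment_estimation_on_normal_draws(self):
        draws = np.random.default_rng(0).normal(0, 1, 100_000)
        pred = make_prediction(draws)
        assert rescaled_deviation(1.96, pred) == pytest.approx(1.96, abs=0.02)

    def test_zero_spread_error_unless_equal(self):
        pred = make_prediction([5.0] * 10)
        assert rescaled_deviation(5.0, pred) == 0.0
        with pytest.raises(ValueError, match="zero spread"):
            rescaled_deviation(6.0, pred)


@pytest.fixture(scope="module")
def pred():
    return make_prediction(np.random.default_rng(1).normal(10, 1, 2000))


class TestClassification:

    def test_inside_ci_is_none_regardless_of_sign(self, pred):
        for observed in (pred.mean - 0.5, pred.mean + 0.5):
            assert classify_interaction(observed, pred, +1).label == "none"

    def test_positive_direction_above_ci_is_synergistic(self, pred):
        call = classify_interaction(pred.ci_high + 1.0, pred, +1)
        assert call.label == "synergistic" and call.dn > 0

    def test_negative_direction_below_ci_is_synergistic(self, pred):
        # e.g. decomposition rate: stress pushes it down, so a joint response
        # below the null CI means the factors reinforce each other
        call = classify_interaction(pred.ci_low - 1.0, pred, -1)
        assert call.label == "synergistic" and call.dn < 0

    def test_antagonistic_branches(self, pred):
        assert classify_interaction(pred.ci_low - 1.0, pred, +1).label == "antagonistic"
        assert classify_interaction(pred.ci_high + 1.0, pred, -1).label == "antagonistic"

    def test_direction_flip_antisymmetry(self, pred):
        # flipping the declared direction swaps synergistic <-> antagonistic
        for observed in (pred.ci_low - 2.0, pred.ci_high + 2.0):
            a = classify_interaction(observed, pred, +1).label
            b = classify_interaction(observed, pred, -1).label
            assert {a, b} == {"synergistic", "antagonistic"}

    def test_invalid_direction_raises(self, pred):
        with pytest.raises(ValueError, match="direction"):
            classify_interaction(10.0, pred, 0)

    def test_calls_table_requires_directions(self, noisy_small):
        _, design, responses = noisy_small
        pred = make_prediction(
            np.random.default_rng(2).normal(10, 1, 100),
            treatment=design.loc[design["kind"] == "multi", "treatment_id"].iloc[0],
            response="ph",
        )
        with pytest.raises(ValueError, match="direction"):
            interaction_calls([pred], responses, directions={})


class TestBestNullSelection:
    def frame(self, observed, preds):
        rows = []
        for model, values in preds.items():
            for i, (o, p) in enumerate(zip(observed, values)):
                rows.append(dict(treatment_id=f"t{i}", response="r", model=model,
                                 observed=o, pred_mean=p, dn=0.0, label="none"))
        return pd.DataFrame(rows)

    def test_exact_generator_has_zero_ssd_and_wins(self):
        obs = [1.0, 2.0, 3.0]
        calls = self.frame(obs, {
            "additive": obs, "multiplicative": [1.1, 2.1, 3.1], "dominative": [0.5, 1.5, 2.5],
        })
        best = select_best_null(calls)
        add = best[(best["model"] == "additive")]
        assert add["ssd"].iloc[0] == 0.0 and add["is_best"].iloc[0]
        assert best["is_best"].sum() == 1

    def test_tie_breaks_to_additive(self):
        obs = [1.0, 2.0]
        calls = self.frame(obs, {m: [1.5, 2.5] for m in ("additive", "multiplicative", "dominative")})
        best = select_best_null(calls)
        assert best.loc[best["is_best"], "model"].tolist() == ["additive"]

    def test_missing_model_raises(self):
        calls = self.frame([1.0], {"additive": [1.0], "multiplicative": [1.0]})
        with pytest.raises(ValueError, match="dominative"):
            select_best_null(calls)


class TestDeviationTests:
    def test_all_zero_dn(self):
        calls = pd.DataFrame({"response": "r", "level": 2, "dn": np.zeros(50)})
        out = deviation_group_tests(calls)
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_shifted_dn_strongly_significant(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame({"response": "r", "level": 5, "dn": 1.0 + 0.01 * rng.normal(size=50)})
        out = deviation_group_tests(calls)
        assert out["p"].iloc[0] < 1e-3

    def test_degenerate_cell_reported_na(self):
        calls = pd.DataFrame({"response": "r", "level": 2, "dn": [1.0]})
        out = deviation_group_tests(calls)
        assert np.isnan(out["t"].iloc[0]) and np.isnan(out["p_adj"].iloc[0])

    def test_rejection_rate_near_nominal_under_null(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            calls = pd.DataFrame({"response": "r", "level": 2, "dn": rng.normal(size=50)})
            if deviation_group_tests(calls)["p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / n_reps == pytest.approx(0.05, abs=0.03)


class TestDnDiCorrelation:
    def test_monotone_gives_rho_one(self):
        calls = pd.DataFrame({
            "treatment_id": [f"t{i}" for i in range(10)], "response": "r",
            "dn": np.arange(10, dtype=float),
        })
        di = pd.DataFrame({
            "treatment_id": [f"t{i}" for i in range(10)], "level": 2,
            "di_norm": np.linspace(0, 1, 10),
        })
        out = dn_vs_di_correlation(calls, di)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        calls = pd.DataFrame({"treatment_id": ["a", "b"], "response": "r", "dn": [0.0, 1.0]})
        di = pd.DataFrame({"treatment_id": ["a", "b"], "level": 2, "di_norm": [0.0, 1.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            dn_vs_di_correlation(calls, di)
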