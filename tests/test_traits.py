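"""All-subsets AICc selection and multimodel averaging."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rhizomix as rx
from rhizomix.traits import CandidateModel


def _ref_frame(values: dict, treatment="R-"):
    rows = []
    for v, traits in values.items():
        for t, val in traits.items():
            rows.append({"variety": v, "treatment": treatment, "trait": t,
                         "value": val})
    return pd.DataFrame(rows)


class TestFeatures:
    def test_mean_and_absdiff_hand_values(self):
        refs = _ref_frame({"a": {"root_area": 400.0}, "b": {"root_area": 100.0}})
        f = rx.build_features(refs, [("a", "b")], "R-", traits=("root_area",))
        assert f["mean_root_area"].iloc[0] == 250.0
        assert f["absdiff_root_area"].iloc[0] == 300.0

    def test_identical_varieties_zero_absdiff(self):
        refs = _ref_frame({"a": {"root_area": 250.0}, "b": {"root_area": 250.0}})
        f = rx.build_features(refs, [("a", "b")], "R-", traits=("root_area",))
        assert f["absdiff_root_area"].iloc[0] == 0.0

    def test_swapping_varieties_leaves_features_unchanged(self):
        refs = _ref_frame({"a": {"root_area": 400.0, "leaf_n": 3.0},
                           "b": {"root_area": 100.0, "leaf_n": 2.5}})
        traits = ("root_area", "leaf_n")
        f1 = rx.build_features(refs, [("a", "b")], "R-", traits=traits)
        f2 = rx.build_features(refs, [("b", "a")], "R-", traits=traits)
        pd.testing.assert_frame_equal(f1, f2)

    def test_missing_reference_drops_mixture(self, caplog):
        refs = _ref_frame({"a": {"root_area": 400.0}})
        with caplog.at_level("WARNING"):
            f = rx.build_features(refs, [("a", "b")], "R-", traits=("root_area",))
        assert f.empty


class TestStandardize:
    def test_z_scores_and_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(3, 7, 40)})
        z = rx.standardize(df)
        assert abs(z["x"].mean()) < 1e-12
        assert z["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        z2 = rx.standardize(z)
        np.testing.assert_allclose(z2["x"], z["x"], atol=1e-12)

    def test_three_point_hand_values(self):
        z = rx.standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])

    def test_constant_column_rejected_by_name(self):
        with pytest.raises(ValueError, match="'c'"):
            rx.standardize(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))


class TestCandidate:
    def test_intercept_only_model(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 30)
        X = pd.DataFrame({"x": rng.normal(0, 1, 30)})
        m = rx.fit_candidate(y, X, ())
        assert m.adj_r2 == pytest.approx(0.0, abs=1e-12)
        assert m.k == 2

    def test_aicc_correction_hand_value(self):
        # k=3 (intercept + 1 slope + variance), n=20: correction 2*3*4/16 = 1.5
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(0, 1, 20)})
        y = 0.5 * X["x"].to_numpy() + rng.normal(0, 1, 20)
        m = rx.fit_candidate(y, X, ("x",))
        aic = -2 * m.loglik + 2 * m.k
        assert m.aicc - aic == pytest.approx(1.5, abs=1e-12)

    def test_single_predictor_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 54)
        y = 0.8 * x + rng.normal(0, 0.5, 54)
        X = pd.DataFrame({"x": x})
        m = rx.fit_candidate(y, X, ("x",))
        n, p = 54, 2
        r2 = 1 - (1 - m.adj_r2) * (n - p) / (n - 1)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_too_small_sample_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 4]})
        with pytest.raises(ValueError, match="too small"):
            rx.fit_candidate(np.array([1.0, 2, 3]), X, ("a", "b"))

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            rx.fit_candidate(rng.normal(0, 1, 30), X, ("a", "b"))


class TestEnumeration:
    def test_all_subsets_of_ten_predictors_evaluated(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(0, 1, (54, 10)),
                         columns=[f"x{i}" for i in range(10)])
        y = X["x0"].to_numpy() + rng.normal(0, 0.5, 54)
        top = rx.enumerate_and_rank(y, X, top=1024)
        assert len(top) == 1024  # 2^10 candidates, all retained when asked
        assert top[0].aicc <= top[-1].aicc

    def test_weights_sum_to_one_and_always_present_term_has_importance_one(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(0, 1, (54, 4)),
                         columns=["a", "b", "c", "d"])
        y = 2.0 * X["a"].to_numpy() + rng.normal(0, 0.3, 54)
        top = rx.enumerate_and_rank(y, X, top=10)
        avg = rx.model_average(top)
        assert sum(m.weight for m in top) == pytest.approx(1.0, abs=1e-12)
        imp = avg.terms.set_index("term")["importance"]
        assert imp["a"] == pytest.approx(1.0, abs=1e-9)

    def test_true_predictor_recovered_under_strong_signal(self):
        hits = 0
        for rep in range(15):
            rng = np.random.default_rng(200 + rep)
            X = pd.DataFrame(rng.normal(0, 1, (54, 8)),
                             columns=[f"x{i}" for i in range(8)])
            y = 1.5 * X["x0"].to_numpy() + rng.normal(0, 1.0, 54)
            best = rx.enumerate_and_rank(y, X, top=1)[0]
            hits += "x0" in best.subset
        assert hits >= 14

    def test_pure_noise_keeps_intercept_only_in_top_set(self):
        in_top = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            X = pd.DataFrame(rng.normal(0, 1, (54, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = rng.normal(0, 1.0, 54)
            top = rx.enumerate_and_rank(y, X, top=10)
            in_top += any(m.subset == () for m in top)
        assert in_top >= 6

    def test_exhaustive_best_beats_backward_selection(self):
        # oracle: a greedy backward AICc pass cannot do better than 2^p
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(0, 1, (40, 6)),
                         columns=[f"x{i}" for i in range(6)])
        y = (X["x1"].to_numpy() - 0.7 * X["x3"].to_numpy()
             + rng.normal(0, 0.8, 40))
        current = tuple(X.columns)
        best_back = rx.fit_candidate(y, X, current)
        improved = True
        while improved and current:
            improved = False
            for drop in current:
                cand = tuple(c for c in current if c != drop)
                m = rx.fit_candidate(y, X, cand)
                if m.aicc < best_back.aicc:
                    best_back, current, improved = m, cand, True
        exhaustive = rx.enumerate_and_rank(y, X, top=1)[0]
        assert exhaustive.aicc <= best_back.aicc + 1e-12

    def test_predictor_rescaling_leaves_standardized_estimates_unchanged(self):
        rng = np.random.default_rng(8)
        raw = pd.DataFrame(rng.normal(0, 1, (54, 3)), columns=["a", "b", "c"])
        y = raw["a"].to_numpy() + rng.normal(0, 0.5, 54)
        z1 = rx.standardize(raw)
        scaled = raw.copy()
        scaled["a"] *= 37.0
        z2 = rx.standardize(scaled)
        m1 = rx.fit_candidate(y, z1, ("a", "b"))
        m2 = rx.fit_candidate(y, z2, ("a", "b"))
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)


def _toy_model(subset, coef, se, aicc, adj_r2=0.5):
    names = ["Intercept"] + list(subset)
    return CandidateModel(
        subset=tuple(subset),
        coef=pd.Series([0.0] + list(coef), index=names),
        se=pd.Series([0.1] + list(se), index=names),
        adj_r2=adj_r2, loglik=0.0, k=len(subset) + 2, aicc=aicc,
    )


class TestAveraging:
    def test_single_model_average_is_itself(self):
        m = _toy_model(["a"], [1.3], [0.2], 100.0)
        avg = rx.model_average([m])
        row = avg.terms.set_index("term").loc["a"]
        assert row["estimate"] == pytest.approx(1.3)
        assert row["importance"] == pytest.approx(1.0)

    def test_two_model_weights_at_delta_two(self):
        m1 = _toy_model(["a"], [1.0], [0.2], 100.0)
        m2 = _toy_model(["b"], [0.5], [0.2], 102.0)
        avg = rx.model_average([m1, m2])
        imp = avg.terms.set_index("term")["importance"]
        assert imp["a"] == pytest.approx(0.731, abs=1e-3)
        assert imp["b"] == pytest.approx(0.269, abs=1e-3)

    def test_full_averaging_zero_substitution_hand_value(self):
        # beta=1.0 in a model of weight 0.75, absent elsewhere -> 0.75
        m1 = _toy_model(["a"], [1.0], [0.0], 100.0)
        m2 = _toy_model(["b"], [0.5], [0.0], 100.0 + 2 * np.log(3.0))
        avg = rx.model_average([m1, m2])  # weights 0.75 / 0.25
        row = avg.terms.set_index("term").loc["a"]
        assert row["estimate"] == pytest.approx(0.75, abs=1e-9)
        assert row["importance"] == pytest.approx(0.75, abs=1e-9)

    def test_conditional_averaging_ignores_absent_models(self):
        m1 = _toy_model(["a"], [1.0], [0.0], 100.0)
        m2 = _toy_model(["b"], [0.5], [0.0], 100.0)
        avg = rx.model_average([m1, m2], mode="conditional")
        row = avg.terms.set_index("term").loc["a"]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["importance"] == pytest.approx(0.5)

    def test_mean_adjusted_r2_reported(self):
        models = [_toy_model(["a"], [1.0], [0.1], 100.0, adj_r2=0.4),
                  _toy_model(["b"], [0.2], [0.1], 101.0, adj_r2=0.6)]
        avg = rx.model_average(models)
        assert avg.mean_adj_r2 == pytest.approx(0.5)
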