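import numpy as np
import pandas as pd
import pytest

from srnzyme.models import (
    FEATURES,
    LinearModel,
    classify,
    fit_lda,
    fit_mlp,
    lda_score,
    load_default_model,
    load_model,
    save_model,
    sensitivity_analysis,
    standardized_coefficients,
)


def _pairs_df(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=list(FEATURES))
    df.insert(0, "class_id", "1.1")
    df.insert(0, "sequence_id", [f"s{i}" for i in range(len(X))])
    df["label"] = y
    return df


class TestLdaScore:
    def test_zero_vector_returns_intercept(self):
        assert lda_score(dict.fromkeys(FEATURES, 0.0)) == pytest.approx(-2.05)

    def test_unit_class_means(self):
        feats = {"Tr3_mean": 1.0, "Tr5_mean": 1.0, "DTr3": 0.0, "DTr5": 0.0}
        assert lda_score(feats) == pytest.approx(-3.80)

    def test_unit_dtr3(self):
        feats = {"Tr3_mean": 0.0, "Tr5_mean": 0.0, "DTr3": 1.0, "DTr5": 0.0}
        assert lda_score(feats) == pytest.approx(-1.04)

    @pytest.mark.parametrize("feature", FEATURES)
    def test_exact_affine_in_each_coordinate(self, feature):
        model = LinearModel()
        base = dict.fromkeys(FEATURES, 0.7)
        bumped = dict(base, **{feature: 0.7 + 2.5})
        delta = lda_score(bumped, model) - lda_score(base, model)
        assert delta == pytest.approx(2.5 * model.coefficients[feature], abs=1e-12)

    def test_missing_feature_errors(self):
        with pytest.raises(KeyError, match="DTr5"):
            lda_score({"Tr3_mean": 0, "Tr5_mean": 0, "DTr3": 0})

    def test_non_finite_feature_errors(self):
        feats = dict.fromkeys(FEATURES, 0.0)
        feats["DTr3"] = float("nan")
        with pytest.raises(ValueError, match="finite"):
            lda_score(feats)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected", [(0.5, 1), (-2.05, -1), (0.0, -1), (1e-9, 1)]
    )
    def test_threshold_rule(self, score, expected):
        assert classify(score) == expected

    def test_invariant_under_joint_positive_rescaling(self):
        rng = np.random.default_rng(0)
        model = LinearModel()
        for c in (0.5, 3.0, 10.0):
            scaled = LinearModel(
                coefficients={k: c * v for k, v in model.coefficients.items()},
                intercept=c * model.intercept,
            )
            for _ in range(20):
                feats = dict(zip(FEATURES, rng.normal(0, 3, 4)))
                assert classify(lda_score(feats, model), 0.0) == classify(
                    lda_score(feats, scaled), 0.0
                )


class TestFitLda:
    def test_recovers_dominant_predictor(self, gaussian_pairs):
        model = fit_lda(gaussian_pairs)
        std = standardized_coefficients(model, gaussian_pairs)
        assert max(std, key=lambda k: abs(std[k])) == "DTr3"
        assert model.coefficients["DTr3"] > 0

    def test_direction_matches_sklearn_discriminant(self, gaussian_pairs):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X = gaussian_pairs[list(FEATURES)].to_numpy()
        y = gaussian_pairs["label"].to_numpy()
        ref = sklearn_lda(solver="lsqr").fit(X, y)
        model = fit_lda(gaussian_pairs)
        w = np.array([model.coefficients[f] for f in FEATURES])
        cos = w @ ref.coef_.ravel() / (
            np.linalg.norm(w) * np.linalg.norm(ref.coef_)
        )
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_identical_distributions_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (200, 4))
        y = np.repeat([1, -1], 100)
        with pytest.warns(UserWarning, match="indistinguishable"):
            fit_lda(_pairs_df(X, y))

    def test_refit_agrees_with_published_rule_on_heldout(self):
        # simulate labels FROM the published decision rule, refit, compare
        rng = np.random.default_rng(7)
        published = LinearModel()
        X = np.column_stack(
            [
                rng.uniform(0, 1, 3000),
                rng.uniform(0, 1, 3000),
                rng.uniform(0, 6, 3000),   # DTr3 drives the sign
                rng.uniform(-1, 1, 3000),
            ]
        )
        scores = np.array(
            [lda_score(dict(zip(FEATURES, row)), published) for row in X]
        )
        keep = np.abs(scores) > 0.25  # margin away from the boundary
        X, scores = X[keep], scores[keep]
        y = np.where(scores > 0, 1, -1)
        train, test = slice(0, len(X) // 2), slice(len(X) // 2, None)
        model = fit_lda(_pairs_df(X[train], y[train]))
        preds = [
            classify(lda_score(dict(zip(FEATURES, row)), model)) for row in X[test]
        ]
        assert (preds == y[test]).mean() >= 0.99

    def test_too_few_records_errors(self):
        X = np.zeros((6, 4))
        y = np.array([1, 1, 1, 1, 1, -1])
        with pytest.raises(ValueError, match="at least 5"):
            fit_lda(_pairs_df(X, y))

    def test_singular_covariance_suggests_ridge(self):
        rng = np.random.default_rng(2)
        X = np.zeros((40, 4))
        X[:, 2] = np.repeat([1.0, -1.0], 20) + rng.normal(0, 0.1, 40)
        y = np.repeat([1, -1], 20)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_lda(_pairs_df(X, y))
        fit_lda(_pairs_df(X, y), ridge=1e-6)  # regularised path succeeds


class TestFitMlp:
    def test_separable_pairs_reach_full_training_accuracy(self, gaussian_pairs):
        # widen the gap so the classes are strictly separable
        wide = gaussian_pairs.copy()
        wide["DTr3"] = wide["DTr3"] + 3.0 * wide["label"]
        model = fit_mlp(wide, hidden=9, seed=0)
        assert model.metadata["train_accuracy"] == 1.0

    def test_xor_beyond_single_hidden_unit(self):
        rng = np.random.default_rng(3)
        base = np.array(
            [[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float
        ).repeat(40, axis=0)
        base += rng.normal(0, 0.05, base.shape)
        X = np.column_stack([base, np.zeros((len(base), 2))])[:, [2, 3, 0, 1]]
        y = np.where(base[:, 0] * base[:, 1] > 0, 1, -1)
        small = fit_mlp(_pairs_df(X, y), hidden=1, seed=0)
        assert small.metadata["train_accuracy"] < 1.0
        big = fit_mlp(_pairs_df(X, y), hidden=9, seed=0)
        assert big.metadata["train_accuracy"] == 1.0

    def test_same_seed_identical_weights(self, gaussian_pairs):
        m1 = fit_mlp(gaussian_pairs, hidden=5, seed=4, max_epochs=300)
        m2 = fit_mlp(gaussian_pairs, hidden=5, seed=4, max_epochs=300)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)

    def test_topology_parameter_budget(self, gaussian_pairs):
        model = fit_mlp(gaussian_pairs, hidden=9, seed=0, max_epochs=50)
        assert model.n_parameters == 4 * 9 + 9 + 9 * 2 + 2 == 65

    def test_nonconvergence_warns_and_returns_best(self, gaussian_pairs):
        with pytest.warns(UserWarning, match="did not converge"):
            model = fit_mlp(gaussian_pairs, hidden=9, seed=0, max_epochs=3)
        assert np.isfinite(model.metadata["final_loss"])

    def test_invalid_hidden_errors(self, gaussian_pairs):
        with pytest.raises(ValueError, match="hidden"):
            fit_mlp(gaussian_pairs, hidden=0)


class TestSensitivityAnalysis:
    def test_single_feature_model_ranks_it_first(self, gaussian_pairs):
        model = LinearModel(
            coefficients={"Tr3_mean": 0.0, "Tr5_mean": 0.0, "DTr3": 2.0, "DTr5": 0.0},
            intercept=0.0,
        )
        sens = sensitivity_analysis(model, gaussian_pairs)
        assert sens.index[0] == "DTr3"

    def test_zero_coefficient_feature_has_unit_sensitivity(self, gaussian_pairs):
        model = LinearModel(
            coefficients={"Tr3_mean": 0.0, "Tr5_mean": 0.0, "DTr3": 2.0, "DTr5": 0.0},
            intercept=0.0,
        )
        sens = sensitivity_analysis(model, gaussian_pairs)
        assert sens["Tr5_mean"] == pytest.approx(1.0)

    def test_planted_importance_ordering_recovered(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (600, 4))
        model = LinearModel(
            coefficients={"Tr3_mean": 4.0, "Tr5_mean": 2.0, "DTr3": 1.0, "DTr5": 0.5},
            intercept=0.0,
        )
        y = np.array([classify(lda_score(dict(zip(FEATURES, r)), model)) for r in X])
        sens = sensitivity_analysis(model, _pairs_df(X, y))
        assert list(sens.index) == ["Tr3_mean", "Tr5_mean", "DTr3", "DTr5"]

    def test_permutation_variant_agrees_on_top_feature(self, gaussian_pairs):
        model = fit_lda(gaussian_pairs)
        mean_sub = sensitivity_analysis(model, gaussian_pairs)
        perm = sensitivity_analysis(model, gaussian_pairs, method="permutation", seed=5)
        assert mean_sub.index[0] == perm.index[0] == "DTr3"

    def test_zero_baseline_floored_with_warning(self):
        X = np.zeros((20, 4))
        X[:10, 2] = 1.0
        y = np.repeat([1, -1], 10)
        exact = LinearModel(
            coefficients={"Tr3_mean": 0.0, "Tr5_mean": 0.0, "DTr3": 2.0, "DTr5": 0.0},
            intercept=-1.0,
        )
        with pytest.warns(UserWarning, match="floor"):
            sens = sensitivity_analysis(exact, _pairs_df(X, y))
        assert np.isfinite(sens).all()

    def test_unknown_method_errors(self, gaussian_pairs):
        with pytest.raises(ValueError, match="method"):
            sensitivity_analysis(LinearModel(), gaussian_pairs, method="drop-column")


class TestPersistence:
    def test_linear_round_trip(self, tmp_path):
        model = LinearModel()
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        assert loaded.coefficients == model.coefficients
        assert loaded.intercept == model.intercept

    def test_mlp_round_trip_preserves_scores(self, tmp_path, gaussian_pairs):
        model = fit_mlp(gaussian_pairs, hidden=4, seed=1, max_epochs=200)
        save_model(model, tmp_path / "mlp.json")
        loaded = load_model(tmp_path / "mlp.json")
        feats = dict(zip(FEATURES, [0.3, -0.2, 1.4, 0.0]))
        assert loaded.score(feats) == pytest.approx(model.score(feats))

    def test_packaged_default_is_published_model(self):
        model = load_default_model()
        assert model.intercept == -2.05
        assert model.coefficients["DTr3"] == 1.01
        assert model.score(dict.fromkeys(FEATURES, 0.0)) == pytest.approx(-2.05)

    def test_unknown_type_errors(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"type": "svm"}')
        with pytest.raises(ValueError, match="svm"):
            load_model(path)
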