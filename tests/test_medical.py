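"""Two-level medical regression: labeling, probabilities, fusion, boosting."""

import numpy as np
import pytest

from capnopred.errors import NotFittedError
from capnopred.medical import (
    MEDICAL_FEATURE_ORDER, feature_importances, fuse_features,
    heuristic_search, label_obstruction, medical_feature_matrix,
    obstruction_probability, predict_medical, train_stage1, train_stage2,
)


@pytest.fixture(scope="module")
def medical_design(cohort300):
    x = medical_feature_matrix(cohort300)
    fev1 = np.array([r.fev1 for r in cohort300])
    fvc = np.array([r.fvc for r in cohort300])
    labels = label_obstruction(fev1, fvc)
    return x, fev1, fvc, labels


@pytest.fixture(scope="module")
def fitted_models(medical_design):
    x, fev1, fvc, labels = medical_design
    tr = np.arange(240)
    stage1 = train_stage1(x[tr], labels[tr], seed=0)
    p = obstruction_probability(stage1, x[tr])
    fused = fuse_features(x[tr], np.clip(p, 1e-12, 1 - 1e-12))
    stage2 = train_stage2(
        fused, fev1[tr], fvc[tr],
        grid=({"n_estimators": 200, "max_depth": 3, "learning_rate": 0.08},),
        seed=0,
    )
    return stage1, stage2


class TestLabelObstruction:
    def test_clearly_obstructed(self):
        assert label_obstruction(2.0, 4.0) is True

    def test_exact_cutoff_is_not_obstructed(self):
        assert label_obstruction(2.8, 4.0) is False

    def test_normal_ratio(self):
        assert label_obstruction(3.5, 4.0) is False

    def test_nonpositive_fvc_rejected(self):
        with pytest.raises(ValueError):
            label_obstruction(1.0, 0.0)


class TestStageOne:
    def test_separable_toy_set_perfect_training_accuracy(self, rng):
        x = np.zeros((20, 15))
        x[:10, 0] = rng.normal(-5, 0.1, 10)
        x[10:, 0] = rng.normal(5, 0.1, 10)
        y = np.array([0] * 10 + [1] * 10)
        model = train_stage1(x, y, seed=0)
        scores = model.decision_score(x)
        assert np.mean((scores > 0).astype(int) == y) == 1.0

    def test_held_out_accuracy_beats_chance(self, medical_design):
        x, _, _, labels = medical_design
        tr, te = np.arange(240), np.arange(240, 300)
        model = train_stage1(x[tr], labels[tr], seed=0)
        acc = np.mean((model.decision_score(x[te]) > 0).astype(int) == labels[te])
        assert acc > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_stage1(np.zeros((5, 15)), np.zeros(5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            train_stage1(np.zeros((0, 15)), np.zeros(0))


class TestObstructionProbability:
    def test_sigmoid_closed_forms(self, fitted_models, medical_design):
        # check the sigmoid transform itself via the model's scores
        x = medical_design[0][:50]
        stage1 = fitted_models[0]
        z = stage1.decision_score(x)
        p = obstruction_probability(stage1, x)
        np.testing.assert_allclose(p, 1.0 / (1.0 + np.exp(-z)))
        assert np.all((p > 0) & (p < 1))

    def test_probability_monotone_in_score(self, fitted_models, medical_design):
        x = medical_design[0]
        stage1 = fitted_models[0]
        z = stage1.decision_score(x)
        p = obstruction_probability(stage1, x)
        order = np.argsort(z)
        assert np.all(np.diff(p[order]) >= 0)


class TestFuseFeatures:
    def test_appends_probability_last(self, rng):
        x = rng.normal(0, 1, (4, 15))
        p = rng.uniform(0.01, 0.99, 4)
        fused = fuse_features(x, p)
        assert fused.shape == (4, 16)
        np.testing.assert_allclose(fused[:, -1], p)
        np.testing.assert_allclose(fused[:, :-1], x)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_features(rng.normal(0, 1, (2, 15)), [0.5, 1.0])


class TestHeuristicSearch:
    def test_single_point_grid_returned_unchanged(self, rng):
        grid = [{"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1}]
        x, y = rng.normal(0, 1, (30, 16)), rng.normal(0, 1, 30)
        assert heuristic_search(grid, x, y, seed=0) == grid[0]

    def test_deterministic_selection(self, rng):
        grid = [
            {"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1},
            {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
        ]
        x = rng.normal(0, 1, (60, 16))
        y = x[:, 0] * 2 + rng.normal(0, 0.1, 60)
        a = heuristic_search(grid, x, y, seed=3)
        b = heuristic_search(grid, x, y, seed=3)
        assert a == b

    def test_recovers_adequate_setting_on_clean_signal(self, rng):
        """On noiseless linear data the search picks a setting that fits it."""
        x = rng.normal(0, 1, (80, 16))
        y = 3.0 + x[:, 0]
        grid = [
            {"n_estimators": 5, "max_depth": 1, "learning_rate": 0.05},
            {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.3},
        ]
        best = heuristic_search(grid, x, y, seed=0)
        assert best["n_estimators"] >= 100

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            heuristic_search([], rng.normal(0, 1, (10, 16)), rng.normal(0, 1, 10))


class TestStageTwo:
    def test_constant_targets_reproduced(self, rng):
        x = rng.normal(0, 1, (40, 16))
        const = np.full(40, 2.5)
        model = train_stage2(
            x, const, const,
            grid=({"n_estimators": 50, "max_depth": 2, "learning_rate": 0.3},),
            seed=0,
        )
        np.testing.assert_allclose(model.booster_fev1.predict(x), 2.5, atol=1e-3)

    def test_too_small_training_set_rejected(self, rng):
        x = rng.normal(0, 1, (5, 16))
        with pytest.raises(ValueError):
            train_stage2(x, np.ones(5), np.ones(5))

    def test_held_out_fvc_r2(self, medical_design, fitted_models):
        from capnopred.metrics import rmse_r2
        x, fev1, fvc, _ = medical_design
        stage1, stage2 = fitted_models
        te = np.arange(240, 300)
        preds = predict_medical(stage1, stage2, x[te])
        _, r2 = rmse_r2(preds[:, 1], fvc[te])
        assert r2 > 0.5

    def test_importances_cover_all_features_and_sum_to_one(self, fitted_models):
        imp = feature_importances(fitted_models[1])
        assert list(imp.index) == list(MEDICAL_FEATURE_ORDER) + ["p_obstruction"]
        assert imp["fev1"].sum() == pytest.approx(1.0)
        assert imp["fvc"].sum() == pytest.approx(1.0)


class TestPredictMedical:
    def test_unfitted_rejected(self, rng):
        with pytest.raises(NotFittedError):
            predict_medical(None, None, rng.normal(0, 1, (2, 15)))

    def test_missing_value_rejected(self, fitted_models, medical_design):
        x = medical_design[0][:3].copy()
        x[1, 4] = np.nan
        with pytest.raises(ValueError):
            predict_medical(*fitted_models, x)

    def test_predictions_positive_and_in_range(self, fitted_models, medical_design):
        x, fev1, fvc, _ = medical_design
        preds = predict_medical(*fitted_models, x[240:300])
        assert np.all(preds > 0)
        assert preds[:, 1].min() > fvc.min() - 1.0
        assert preds[:, 1].max() < fvc.max() + 1.0

    def test_overfit_config_interpolates_training_subject(self, medical_design):
        x, fev1, fvc, labels = medical_design
        tr = np.arange(100)
        stage1 = train_stage1(x[tr], labels[tr], seed=0)
        p = obstruction_probability(stage1, x[tr])
        fused = fuse_features(x[tr], np.clip(p, 1e-12, 1 - 1e-12))
        stage2 = train_stage2(
            fused, fev1[tr], fvc[tr],
            grid=({"n_estimators": 800, "max_depth": 8, "learning_rate": 0.3},),
            seed=0,
        )
        preds = predict_medical(stage1, stage2, x[tr][:5])
        assert np.all(np.abs(preds[:, 0] - fev1[tr][:5]) < 0.05)
        assert np.all(np.abs(preds[:, 1] - fvc[tr][:5]) < 0.05)

    def test_deterministic(self, medical_design):
        x, fev1, fvc, labels = medical_design
        tr = np.arange(120)
        outs = []
        for _ in range(2):
            s1 = train_stage1(x[tr], labels[tr], seed=4)
            p = obstruction_probability(s1, x[tr])
            fused = fuse_features(x[tr], np.clip(p, 1e-12, 1 - 1e-12))
            s2 = train_stage2(
                fused, fev1[tr], fvc[tr],
                grid=({"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},),
                seed=4,
            )
            outs.append(predict_medical(s1, s2, x[tr][:10]))
        np.testing.assert_array_equal(outs[0], outs[1])
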