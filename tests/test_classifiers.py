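"""From-scratch classifiers against closed-form properties and established
reference implementations (scikit-learn, used only as a cross-check oracle)."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

import fsrgesture as fg
from fsrgesture.classifiers import _smo_linear, svm_objective
from fsrgesture.features import feature_columns

from conftest import make_feature_database


def tiny_db(X, y):
    frame = pd.DataFrame(X, columns=feature_columns()[: X.shape[1]])
    frame["label"] = y
    mask = (1,) if X.shape[1] == 2 else (1, 2, 3)
    cols = fg.feature_columns(mask)
    frame.columns = cols + ["label"]
    return fg.GestureDatabase(frame, sensor_mask=mask)


#: Four linearly separable 2-D points used by the separable-case tests.
TOY_X = np.array([[0.0, 0.0], [0.2, 0.1], [1.0, 1.0], [0.9, 1.2]])
TOY_Y = np.array([0, 0, 1, 1])


class TestLda:
    def test_boundary_is_perpendicular_bisector_for_symmetric_classes(self):
        """Two classes with identical covariance and means +-m: the decision
        boundary is the perpendicular bisector hyperplane, so the midpoint
        scores equally and points off-axis classify by their mean side."""
        rng = np.random.default_rng(0)
        cloud = rng.normal(0, 0.1, size=(50, 6))
        m = np.full(6, 0.5)
        X = np.vstack([cloud - m, cloud + m])
        y = np.array([0] * 50 + [1] * 50)
        model = fg.train_lda(tiny_db(X, y))
        coef, intercept = model.params["coef"], model.params["intercept"]
        mid = X.mean(axis=0)  # midpoint of the two class means
        scores_mid = mid @ coef.T + intercept
        assert scores_mid[0] == pytest.approx(scores_mid[1], abs=1e-9)
        assert model.predict((mid - 0.1 * m)[None])[0] == 0
        assert model.predict((mid + 0.1 * m)[None])[0] == 1

    def test_training_accuracy_perfect_on_default_cohort(self, cohort_dbs):
        for db in cohort_dbs:
            model = fg.train_lda(db)
            assert np.mean(model.predict_db(db) == db.y) == 1.0

    def test_class_with_single_row_rejected(self):
        X = np.vstack([TOY_X, [[2.0, 2.0]]])
        y = np.array([0, 0, 1, 1, 2])
        with pytest.raises(fg.TrainingError):
            fg.train_lda(tiny_db(X, y))


class TestQda:
    def test_reduces_to_lda_when_class_covariances_equal(self):
        """Classes built as shifted copies of one point cloud have identical
        sample covariances, so QDA and LDA predict identically."""
        rng = np.random.default_rng(1)
        cloud = rng.normal(0, 0.3, size=(30, 6))
        shifts = [np.zeros(6), np.full(6, 1.0), np.r_[np.full(3, -1.0), np.zeros(3)]]
        X = np.vstack([cloud + s for s in shifts])
        y = np.repeat([0, 1, 2], 30)
        db = tiny_db(X, y)
        grid = rng.normal(0.2, 0.8, size=(200, 6))
        assert np.array_equal(
            fg.train_qda(db).predict(grid), fg.train_lda(db).predict(grid)
        )


class TestKnn:
    def test_one_nn_training_accuracy_is_perfect_on_distinct_rows(self, db0):
        model = fg.train_knn(db0, k=1)
        assert np.mean(model.predict_db(db0) == db0.y) == 1.0

    def test_distance_tie_breaks_to_lowest_code(self):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 1.0], [1.0, -1.0]])
        y = np.array([3, 1, 3, 1])
        model = fg.train_knn(tiny_db(X, y), k=2)
        # query equidistant from one row of each class
        assert model.predict(np.array([[0.0, 0.0]]))[0] == 1


class TestLinearSvm:
    def test_separable_toy_has_zero_training_errors(self):
        model = fg.train_linear_svm(tiny_db(TOY_X, TOY_Y))
        assert np.array_equal(model.predict(TOY_X), TOY_Y)

    def test_pairwise_objective_matches_reference_qp(self):
        """Primal objective of each SMO solution within 1e-3 relative of the
        reference QP solver's optimum on a 40-row two-class problem."""
        db = make_feature_database(3, n_classes=2, rows_per_class=20)
        X, y = db.X, np.where(db.y == 0, 1.0, -1.0)
        for C in (0.1, 1.0, 10.0):
            w, b = _smo_linear(X, y, C)
            ref = SVC(C=C, kernel="linear").fit(X, y)
            mine = svm_objective(w, b, X, y, C)
            theirs = svm_objective(ref.coef_[0], ref.intercept_[0], X, y, C)
            assert mine == pytest.approx(theirs, rel=1e-3)
            assert mine <= theirs * (1 + 1e-6)  # never worse than the oracle

    def test_feature_scaling_with_rescaled_C_keeps_boundary_direction(self):
        """Scaling features by 10 and C by 1/100 leaves the separable-case
        boundary direction unchanged (w scales by 1/10)."""
        w1, b1 = _smo_linear(TOY_X, np.where(TOY_Y == 0, 1.0, -1.0), C=100.0)
        w2, b2 = _smo_linear(10 * TOY_X, np.where(TOY_Y == 0, 1.0, -1.0), C=1.0)
        assert w2 / np.linalg.norm(w2) == pytest.approx(w1 / np.linalg.norm(w1), abs=1e-4)

    def test_vote_count_structure(self, db0):
        model = fg.train_linear_svm(db0)
        assert len(model.params["pairs"]) == 8 * 7 // 2


@pytest.mark.parametrize(
    "trainer,oracle",
    [
        (fg.train_lda, lambda: LinearDiscriminantAnalysis()),
        (fg.train_qda, lambda: QuadraticDiscriminantAnalysis()),
        (lambda db: fg.train_knn(db, 1), lambda: KNeighborsClassifier(1)),
        (fg.train_linear_svm, lambda: SVC(C=1.0, kernel="linear")),
    ],
    ids=["lda", "qda", "knn", "linear_svm"],
)
def test_oracle_agreement_over_20_seeded_databases(trainer, oracle):
    """Each from-scratch classifier agrees with the established reference
    implementation on >= 99% of rows, pooled over 20 seeded databases with
    overlapping class clusters."""
    agree = total = 0
    for seed in range(20):
        db = make_feature_database(seed, rows_per_class=15)
        mine = trainer(db).predict(db.X)
        theirs = oracle().fit(db.X, db.y).predict(db.X)
        agree += int(np.sum(mine == theirs))
        total += db.n_rows
    assert agree / total >= 0.99


class TestSerialization:
    @pytest.mark.parametrize("name", ["lda", "qda", "knn", "linear_svm"])
    def test_json_round_trip_predicts_identically(self, tmp_path, db0, name):
        from fsrgesture import io as fio

        model = fg.TRAINERS[name](db0)
        path = tmp_path / "model.json"
        fio.write_model(path, model)
        loaded = fio.read_model(path)
        assert loaded.kind == model.kind
        assert np.array_equal(loaded.predict_db(db0), model.predict_db(db0))

    def test_plugin_models_are_not_serializable(self, tmp_path, db0):
        from fsrgesture import io as fio

        model = fg.plugin_model(lambda X: np.zeros(len(X)), db0.classes, db0.feature_names)
        with pytest.raises(ValueError):
            fio.write_model(tmp_path / "m.json", model)

    def test_plugin_model_delegates_prediction(self, db0):
        oracle = SVC(C=1.0, kernel="rbf").fit(db0.X, db0.y)
        model = fg.plugin_model(oracle.predict, db0.classes, db0.feature_names, "rbf_svm")
        assert np.mean(model.predict_db(db0) == db0.y) > 0.9
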