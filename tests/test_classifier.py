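"""State classifier: training determinism, the 2x confidence rule and its
boundary, held-out evaluation, LDA projection, trial gating, serialization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from ictaloop import classifier as clf
from ictaloop.features import FEATURE_NAMES
from ictaloop.types import StateLabel, StimulationEvent

N_FEAT = len(FEATURE_NAMES)
FOUR_STATES = [
    StateLabel.BASELINE,
    StateLabel.S1_INTERICTAL,
    StateLabel.S2_ICTAL,
    StateLabel.S3_CONTINUOUS,
]


def _toy_separable(n_per_class=20, seed=0):
    """Two classes separated in feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, N_FEAT)) * 0.01
    X[n_per_class:, 0] += 5.0
    y = [StateLabel.BASELINE] * n_per_class + [StateLabel.S2_ICTAL] * n_per_class
    return X, y


class _FakeEstimator:
    """Fixed-output stand-in to exercise the confidence rule and metrics."""

    def __init__(self, proba_rows, classes):
        self._p = np.asarray(proba_rows, float)
        self.classes_ = np.array([c.value for c in classes])

    def predict_proba(self, X):
        return self._p[: len(np.atleast_2d(X))]

    def predict(self, X):
        return self.classes_[np.argmax(self._p[: len(np.atleast_2d(X))], axis=1)]


def _fake_model(proba_rows):
    est = _FakeEstimator(proba_rows, FOUR_STATES)
    return clf.StateModel(estimator=est, classes=list(FOUR_STATES))


class TestTrain:
    def test_linearly_separable_toy_set_trains_perfectly(self):
        X, y = _toy_separable()
        model = clf.train(X, y, seed=0, n_estimators=25)
        pred = model.estimator.predict(X)
        assert (pred == [lab.value for lab in y]).mean() == 1.0

    def test_same_seed_same_predictions(self, rng):
        X, y = _toy_separable(seed=3)
        probe = rng.normal(size=(30, N_FEAT))
        a = clf.train(X, y, seed=7, n_estimators=25).estimator.predict_proba(probe)
        b = clf.train(X, y, seed=7, n_estimators=25).estimator.predict_proba(probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X = np.zeros((10, N_FEAT))
        with pytest.raises(ValueError, match="two classes"):
            clf.train(X, [StateLabel.BASELINE] * 10, seed=0)

    def test_mixed_label_rejected(self):
        X = np.zeros((4, N_FEAT))
        y = [StateLabel.BASELINE, StateLabel.MIXED, StateLabel.S2_ICTAL, StateLabel.S2_ICTAL]
        with pytest.raises(ValueError, match="MIXED"):
            clf.train(X, y, seed=0)


class TestConfidenceRule:
    def test_certain_prediction_is_confident(self):
        res = clf.classify_epoch(_fake_model([[1.0, 0.0, 0.0, 0.0]]), np.zeros(N_FEAT))
        assert res.confident and res.label is StateLabel.BASELINE

    def test_below_twice_runner_up_is_mixed(self):
        res = clf.classify_epoch(
            _fake_model([[0.40, 0.30, 0.20, 0.10]]), np.zeros(N_FEAT)
        )
        assert not res.confident
        assert res.label is StateLabel.MIXED

    def test_exactly_twice_runner_up_is_confident(self):
        res = clf.classify_epoch(
            _fake_model([[0.50, 0.25, 0.15, 0.10]]), np.zeros(N_FEAT)
        )
        assert res.confident and res.label is StateLabel.BASELINE

    def test_rule_is_scale_free(self):
        for scale in (1.0, 0.2, 7.0):
            p = np.array([0.4, 0.3, 0.2, 0.1]) * scale
            label, confident = clf._apply_confidence_rule(p, FOUR_STATES)
            assert not confident and label is StateLabel.MIXED

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValueError, match="expected 20 features"):
            clf.classify_epoch(_fake_model([[1, 0, 0, 0]]), np.zeros(7))

    def test_probabilities_sum_to_one(self, small_state_model):
        model, _ = small_state_model
        fv = np.random.default_rng(1).normal(size=(10, N_FEAT))
        for res in clf.classify_features(model, fv):
            assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-9)


class TestEvaluate:
    def test_perfect_predictions_give_f1_one(self):
        X, y = _toy_separable()
        model = clf.train(X, y, seed=0, n_estimators=25)
        assert clf.evaluate(model, X, y)["macro_f1"] == 1.0

    def test_all_one_class_on_balanced_four_class_set(self):
        # hand-computed confusion matrix: predicted class has precision
        # 1/4 and recall 1 (f1 = 0.4); the other three classes score 0,
        # so macro f1 = 0.4 / 4 = 0.1
        y = FOUR_STATES * 10
        proba = np.tile([1.0, 0.0, 0.0, 0.0], (40, 1))
        model = _fake_model(proba)
        out = clf.evaluate(model, np.zeros((40, N_FEAT)), y)
        assert out["macro_f1"] == pytest.approx(0.1)

    def test_empty_test_set_rejected(self, small_state_model):
        model, _ = small_state_model
        with pytest.raises(ValueError, match="empty"):
            clf.evaluate(model, np.zeros((0, N_FEAT)), [])

    def test_held_out_animals_f1_above_09(self, small_state_model):
        _, evaluation = small_state_model
        assert evaluation["macro_f1"] > 0.9
        assert set(evaluation["roc"]) == {c.value for c in FOUR_STATES}


class TestLdaProjection:
    @staticmethod
    def _clusters(seed=0, sep=6.0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for i, lab in enumerate(FOUR_STATES):
            c = rng.normal(size=N_FEAT) * 0 + np.eye(N_FEAT)[i] * sep
            X.append(rng.normal(size=(30, N_FEAT)) + c)
            y += [lab] * 30
        return np.vstack(X), y

    def test_projection_separates_better_than_random(self):
        X, y = self._clusters()
        Z = clf.lda_project(X, y)
        assert Z.shape == (len(X), 3)
        rng = np.random.default_rng(0)
        R = X @ rng.normal(size=(N_FEAT, 3))
        labels = [lab.value for lab in y]
        assert silhouette_score(Z, labels) > silhouette_score(R, labels)

    def test_duplicated_columns_are_handled(self):
        X, y = self._clusters()
        X_dup = X.copy()
        X_dup[:, 5] = X_dup[:, 4]  # rank-deficient scatter
        Z = clf.lda_project(X_dup, y)
        assert np.all(np.isfinite(Z))

    def test_permuted_labels_destroy_separation(self):
        X, y = self._clusters()
        Z = clf.lda_project(X, y)
        rng = np.random.default_rng(1)
        y_perm = list(rng.permutation([lab.value for lab in y]))
        Zp = clf.lda_project(X, [StateLabel(v) for v in y_perm])
        labels = [lab.value for lab in y]
        assert silhouette_score(Z, labels) > silhouette_score(Zp, y_perm) + 0.3

    def test_three_classes_yield_two_discriminants_with_warning(self):
        X, y = self._clusters()
        keep = [i for i, lab in enumerate(y) if lab is not StateLabel.S3_CONTINUOUS]
        with pytest.warns(UserWarning, match="discriminants"):
            Z = clf.lda_project(X[keep], [y[i] for i in keep])
        assert Z.shape[1] == 2


class TestGating:
    def test_state2_pre_epochs_pass_the_gate(self, small_state_model, pv0_session):
        model, _ = small_state_model
        from ictaloop.features import minmax_scale

        recording, stims = pv0_session
        scaled = minmax_scale(recording)
        triggered = [s for s in stims if s.triggered]
        passed = [clf.gate_pre_stimulation(model, scaled, s) for s in triggered]
        assert np.mean(passed) > 0.8  # sessions are wall-to-wall State 2

    def test_insufficient_pre_trigger_data_rejected(self, small_state_model, pv0_session):
        model, _ = small_state_model
        from ictaloop.features import minmax_scale

        recording, _ = pv0_session
        early = StimulationEvent(
            detection_time=4.0, delay=0.0, delay_class="0", light_on=4.0, triggered=True
        )
        assert clf.gate_pre_stimulation(model, minmax_scale(recording), early) is False


class TestSerialization:
    def test_round_trip(self, small_state_model, tmp_path):
        model, _ = small_state_model
        path = tmp_path / "model.joblib"
        clf.save_model(model, path)
        loaded = clf.load_model(path)
        assert loaded.classes == model.classes
        probe = np.random.default_rng(0).normal(size=(5, N_FEAT))
        assert np.array_equal(
            loaded.estimator.predict_proba(probe), model.estimator.predict_proba(probe)
        )

    def test_feature_name_mismatch_refused(self, small_state_model, tmp_path):
        import joblib

        model, _ = small_state_model
        path = tmp_path / "model.joblib"
        clf.save_model(model, path)
        blob = joblib.load(path)
        blob["feature_names"][3] = "renamed"
        joblib.dump(blob, path)
        with pytest.raises(ValueError, match="feature names"):
            clf.load_model(path)
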