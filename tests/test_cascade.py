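"""Cascade ensemble: split plans, routing pools and the training protocol."""

import numpy as np
import pytest
from sklearn.svm import SVC

from errorcascade import (
    CascadeEnsembleClassifier,
    RecordTable,
    fit_cascade,
    fit_stage1,
    generate,
    pima_like_spec,
    predict_cascade,
    route_stage1,
    split_train_eval,
)
from errorcascade.learners import LearnerSpec, fit_learner
from errorcascade.lda import ScatterLDA


class FixedPredictor:
    """Stub learner returning a preset label sequence (for routing tests)."""

    def __init__(self, labels):
        self.labels = np.asarray(labels)
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.labels[: X.shape[0]]


class ConstantPredictor:
    """Stub learner always predicting one label."""

    def __init__(self, label):
        self.label = label
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.label)


class TestSplitTrainEval:
    def test_seventy_thirty_split_sizes(self, clean_gaussian_table):
        table = clean_gaussian_table.take(np.arange(100))
        plan = split_train_eval(table, fraction=0.7, seed=0)
        assert len(plan.train_indices) == 70
        assert len(plan.eval_indices) == 30
        combined = np.union1d(plan.train_indices, plan.eval_indices)
        np.testing.assert_array_equal(combined, np.arange(100))

    def test_same_seed_identical_plans(self, clean_gaussian_table):
        a = split_train_eval(clean_gaussian_table, seed=3)
        b = split_train_eval(clean_gaussian_table, seed=3)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_stratified_split_preserves_class_ratio(self, rng):
        labels = np.array([0] * 60 + [1] * 40)
        table = RecordTable(rng.normal(size=(100, 2)), labels, ("x", "y"))
        plan = split_train_eval(table, fraction=0.7, stratified=True, seed=1)
        eval_labels = labels[plan.eval_indices]
        # 30 eval records at 60:40 -> 18 negatives, 12 positives, +/-1
        assert abs((eval_labels == 1).sum() - 12) <= 1

    def test_bad_fraction_rejected(self, clean_gaussian_table):
        with pytest.raises(ValueError):
            split_train_eval(clean_gaussian_table, fraction=1.0)


class TestRouting:
    def test_truth_table_enumeration(self):
        """8-instance correctness pattern enumerating all NB/KNN/J48
        right/wrong combinations; pools checked against the per-instance
        pairwise rule computed independently."""
        y = np.zeros(8, dtype=int)
        # predictions equal y where the learner should be 'correct'
        nb_ok = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        knn_ok = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=bool)
        j48_ok = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
        learners = {
            "nb": FixedPredictor(np.where(nb_ok, y, 1 - y)),
            "knn": FixedPredictor(np.where(knn_ok, y, 1 - y)),
            "j48": FixedPredictor(np.where(j48_ok, y, 1 - y)),
        }
        table = RecordTable(np.zeros((8, 1)), y, ("x",))
        part = route_stage1(learners, table)
        expected_a = [i for i in range(8) if nb_ok[i] and knn_ok[i]]
        expected_b = [i for i in range(8) if knn_ok[i] and j48_ok[i]]
        expected_f = [
            i
            for i in range(8)
            if not (nb_ok[i] and knn_ok[i]) and not (knn_ok[i] and j48_ok[i])
        ]
        assert list(part.pool_a) == expected_a == [0, 1]
        assert list(part.pool_b) == expected_b == [0, 4]
        assert list(part.pool_f) == expected_f == [2, 3, 5, 6, 7]

    def test_all_correct_gives_empty_false_pool(self):
        y = np.array([0, 1, 0, 1])
        learners = {k: FixedPredictor(y) for k in ("nb", "knn", "j48")}
        table = RecordTable(np.zeros((4, 1)), y, ("x",))
        part = route_stage1(learners, table)
        assert list(part.pool_a) == [0, 1, 2, 3]
        assert part.pool_f.size == 0

    def test_all_wrong_routes_everything_to_false_pool(self):
        y = np.array([0, 1, 0, 1])
        learners = {k: FixedPredictor(1 - y) for k in ("nb", "knn", "j48")}
        table = RecordTable(np.zeros((4, 1)), y, ("x",))
        part = route_stage1(learners, table)
        assert part.pool_a.size == 0 and part.pool_b.size == 0
        assert list(part.pool_f) == [0, 1, 2, 3]

    def test_empty_routing_table_rejected(self):
        learners = {k: FixedPredictor([0]) for k in ("nb", "knn", "j48")}
        table = RecordTable(np.zeros((1, 1)), np.array([0]), ("x",))
        with pytest.raises(ValueError, match="empty"):
            route_stage1(learners, table.take(np.array([], dtype=int)))


class TestFitStage1:
    def test_separable_data_all_three_perfect(self):
        X = np.array([[0.0, 0], [0.5, 0], [0.2, 0], [10, 0], [10.5, 0], [10.2, 0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        table = RecordTable(X, y, ("x", "y"))
        learners = fit_stage1(table)
        for model in learners.values():
            assert (model.predict(X) == y).all()

    def test_noise_labels_route_near_majority_rate(self, rng):
        X = rng.normal(size=(400, 3))
        y = rng.integers(0, 2, 400)  # labels independent of features
        table = RecordTable(X, y, ("a", "b", "c"))
        learners = fit_stage1(table)
        held_X = rng.normal(size=(400, 3))
        held_y = rng.integers(0, 2, 400)
        majority = max(held_y.mean(), 1 - held_y.mean())
        for model in learners.values():
            acc = (model.predict(held_X) == held_y).mean()
            assert abs(acc - 0.5) < 0.1  # no structure to learn
            assert acc <= majority + 0.1

    def test_wrong_roster_rejected(self, toy_table):
        with pytest.raises(ValueError, match="exactly"):
            fit_stage1(toy_table, {"nb": LearnerSpec("NB")})


class TestCascadeFit:
    def test_pools_cover_routing_set_disjointly(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=2).fit(t.features, t.labels)
        p = clf.partition_
        in_ab = np.union1d(p.pool_a, p.pool_b)
        assert np.intersect1d(in_ab, p.pool_f).size == 0
        np.testing.assert_array_equal(
            np.union1d(in_ab, p.pool_f), np.sort(p.routing_indices)
        )

    def test_stage3_indices_stay_inside_routing_set(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=2).fit(t.features, t.labels)
        assert np.isin(
            clf.stage3_training_indices_, clf.partition_.routing_indices
        ).all()

    def test_fit_is_deterministic(self, clean_gaussian_table):
        t = clean_gaussian_table
        a = CascadeEnsembleClassifier(random_state=9).fit(t.features, t.labels)
        b = CascadeEnsembleClassifier(random_state=9).fit(t.features, t.labels)
        np.testing.assert_array_equal(
            a.stage3_training_indices_, b.stage3_training_indices_
        )
        np.testing.assert_array_equal(
            a.predict(t.features), b.predict(t.features)
        )

    def test_perfect_stage1_empties_false_pool(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (60, 2)), rng.normal(8, 0.3, (60, 2))])
        y = np.array([0] * 60 + [1] * 60)
        clf = CascadeEnsembleClassifier(use_lda=False, random_state=0).fit(X, y)
        part = clf.partition_
        assert part.pool_f.size == 0
        # stage-III set is then exactly the stage-II-correct instances
        assert np.isin(
            clf.stage3_training_indices_, part.routing_indices
        ).all()
        assert (clf.predict(X) == y).all()

    def test_constant_stage1_reduces_to_plain_svm(self, clean_gaussian_table):
        """With majority-constant stage-I learners every routing instance
        lands in the stage-III set, so the cascade equals an SVM fit on
        the whole routing set."""
        t = clean_gaussian_table
        overrides = {
            "nb": lambda: ConstantPredictor(0),
            "knn": lambda: ConstantPredictor(0),
            "j48": lambda: ConstantPredictor(0),
        }
        clf = CascadeEnsembleClassifier(
            use_lda=False, stage1_overrides=overrides, random_state=1
        ).fit(t.features, t.labels)
        route_idx = clf.partition_.routing_indices
        np.testing.assert_array_equal(
            clf.stage3_training_indices_, np.sort(route_idx)
        )
        plain = SVC(kernel="linear", C=1.0).fit(
            t.features[route_idx], t.labels[route_idx]
        )
        np.testing.assert_array_equal(
            clf.predict(t.features), plain.predict(t.features)
        )

    def test_lda_cascade_runs_on_one_axis(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(use_lda=True, random_state=0).fit(
            t.features, t.labels
        )
        assert clf.lda_.components_.shape == (t.d, 1)
        pred = clf.predict(t.features)
        assert set(np.unique(pred)) <= {0, 1}

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="two classes"):
            CascadeEnsembleClassifier().fit(X, np.zeros(50, dtype=int))

    def test_smote_option_runs(self, rng):
        X = np.vstack([rng.normal(0, 1, (160, 2)), rng.normal(2, 1, (60, 2))])
        y = np.array([0] * 160 + [1] * 60)
        clf = CascadeEnsembleClassifier(
            use_lda=False, smote=True, random_state=0
        ).fit(X, y)
        assert clf.predict(X).shape == (220,)


class TestCascadePredict:
    def test_matches_stored_stage3_svm_directly(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=5).fit(t.features, t.labels)
        direct = clf.stage3_.predict(clf.lda_.transform(t.features))
        np.testing.assert_array_equal(clf.predict(t.features), direct)

    def test_single_record(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=5).fit(t.features, t.labels)
        pred = clf.predict(t.features[:1])
        assert pred.shape == (1,) and pred[0] in (0, 1)

    def test_repeated_inference_bitwise_identical(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=5).fit(t.features, t.labels)
        np.testing.assert_array_equal(
            clf.decision_function(t.features), clf.decision_function(t.features)
        )

    def test_dimension_mismatch_rejected(self, clean_gaussian_table):
        t = clean_gaussian_table
        clf = CascadeEnsembleClassifier(random_state=5).fit(t.features, t.labels)
        with pytest.raises(ValueError, match="features"):
            clf.predict(t.features[:, :3])

    def test_noninferior_to_stage1_learners_on_test_split(self):
        """On a fixed generated split the cascade's test accuracy is within
        2 points of every stage-I learner trained on the same data."""
        spec = pima_like_spec(
            n=2500, class_prior=0.5, zero_inflation={}, seed=0
        )
        t = generate(spec)
        Xtr, ytr = t.features[:2000], t.labels[:2000]
        Xte, yte = t.features[2000:], t.labels[2000:]
        cascade = CascadeEnsembleClassifier(random_state=0).fit(Xtr, ytr)
        cascade_acc = (cascade.predict(Xte) == yte).mean()
        lda = ScatterLDA().fit(Xtr, ytr)
        for kind in ("NB", "KNN", "J48"):
            model = fit_learner(
                LearnerSpec(kind, seed=0), lda.transform(Xtr), ytr
            )
            acc = (model.predict(lda.transform(Xte)) == yte).mean()
            assert cascade_acc >= acc - 0.02


class TestProtocolWrappers:
    def test_fit_cascade_uses_seventy_thirty_split(self, clean_gaussian_table):
        t = clean_gaussian_table
        model = fit_cascade(t, {"seed": 7})
        assert len(model.plan.train_indices) == round(0.7 * t.n)
        preds = predict_cascade(model, t.features[model.plan.eval_indices])
        assert preds.shape == model.plan.eval_indices.shape

    def test_no_eval_instance_reaches_fitting(self, clean_gaussian_table):
        t = clean_gaussian_table
        model = fit_cascade(t, {"seed": 7})
        # stage-III indices are positions within the training partition
        assert model.classifier.stage3_training_indices_.max() < len(
            model.plan.train_indices
        )
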