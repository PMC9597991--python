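"""Base classifiers, voting/stacking combiners, and the composite predictor."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

import acrstack as ak
from acrstack.models import (
    ClassifierSpec,
    EnsembleVoteClassifier,
    FeatureAveragedClassifier,
    ScoreTable,
    StackingEnsembleClassifier,
    average_scores,
    make_base_classifier,
    stack_feature_matrices,
)
from acrstack.records import FeatureMatrix


class ConstantStub(ClassifierMixin, BaseEstimator):
    """Classifier emitting a fixed positive-class probability for every sample."""

    def __init__(self, proba: float = 0.5):
        self.proba = proba

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.full(np.asarray(X).shape[0], self.proba)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class FirstColumnStub(ConstantStub):
    """Emits X[:, 0] (clipped to [0,1]) as the positive-class probability."""

    def predict_proba(self, X):
        p = np.clip(np.asarray(X)[:, 0], 0.0, 1.0)
        return np.column_stack([1 - p, p])


class MemorizerStub(ConstantStub):
    """Returns the training label for rows seen during fit, 0.5 otherwise.

    Makes information leakage from training folds into out-of-fold
    meta-features directly observable.
    """

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        self.seen_ = {tuple(row): label for row, label in zip(np.asarray(X), y)}
        return self

    def predict_proba(self, X):
        p = np.array([self.seen_.get(tuple(row), 0.5) for row in np.asarray(X)],
                     dtype=float)
        return np.column_stack([1 - p, p])


def separable_fm(n_per_class: int, n_features: int = 2, gap: float = 4.0,
                 seed: int = 1):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_per_class, n_features))
    X1 = rng.standard_normal((n_per_class, n_features)) + gap
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    fm = FeatureMatrix([f"s{i}" for i in range(2 * n_per_class)], X,
                       [f"f{j}" for j in range(n_features)])
    return fm, y


class TestBaseClassifiers:
    def test_svm_separable_training_accuracy(self):
        fm, y = separable_fm(30, seed=1)
        model = ak.train_base(ClassifierSpec("svm", seed=1), fm, y)
        scores = ak.predict_scores(model, fm).scores
        assert np.mean((scores >= 0.5).astype(int) == y) == 1.0

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("catapult")

    def test_single_class_labels_raise(self):
        fm, y = separable_fm(10)
        with pytest.raises(ValueError, match="single class"):
            ak.train_base(ClassifierSpec("lr"), fm, np.ones_like(y))

    def test_label_permutation_null_auc(self):
        # permuted labels carry no signal: held-out AUC should hover near 0.5
        rng = np.random.default_rng(0)
        fm, y = separable_fm(100, seed=3)
        y_perm = rng.permutation(y)
        train, test = np.arange(0, 200, 2), np.arange(1, 200, 2)
        model = ak.train_base(
            ClassifierSpec("lr", seed=0), fm.subset_columns([0, 1]), y_perm
        )
        est = model.estimator
        # refit on even rows, evaluate on odd rows
        est.fit(fm.data[train], y_perm[train])
        scores = est.predict_proba(fm.data[test])[:, 1]
        auc = ak.evaluate_predictions(y_perm[test], scores).AUC
        assert 0.35 <= auc <= 0.65

    def test_grid_search_wraps_when_tuned(self):
        est = make_base_classifier(ClassifierSpec("knn", tune=True), n_features=40)
        from sklearn.model_selection import GridSearchCV

        assert isinstance(est, GridSearchCV)
        assert max(est.param_grid["n_neighbors"]) == 20  # max(sqrt(40), 40/2)
        assert len(est.param_grid["n_neighbors"]) <= 30

    def test_all_eight_members_fit_and_score(self):
        fm, y = separable_fm(15, seed=5)
        for name in ak.BASE_CLASSIFIERS:
            model = ak.train_base(ClassifierSpec(name, seed=0), fm, y)
            scores = ak.predict_scores(model, fm).scores
            assert np.all((scores >= 0) & (scores <= 1)), name


class TestVoteEnsemble:
    def _vote(self, probas):
        members = [(f"m{i}", ConstantStub(p)) for i, p in enumerate(probas)]
        fm, y = separable_fm(6)
        est = EnsembleVoteClassifier(members=members).fit(fm.data, y)
        return est

    def test_unanimous_positive(self):
        est = self._vote([0.9] * 8)
        assert np.all(est.predict(np.zeros((3, 2))) == 1)

    def test_majority_five_of_eight(self):
        est = self._vote([0.9] * 5 + [0.1] * 3)
        assert np.all(est.predict(np.zeros((2, 2))) == 1)

    def test_tie_resolved_by_mean_probability(self):
        # 4-4 split with mean probability 0.62 -> positive
        est = self._vote([0.95] * 4 + [0.29] * 4)
        mean_p = est.predict_proba(np.zeros((1, 2)))[0, 1]
        assert mean_p == pytest.approx(0.62)
        assert est.predict(np.zeros((1, 2)))[0] == 1
        # and a tie below 0.5 -> negative
        est_low = self._vote([0.55] * 4 + [0.05] * 4)
        assert est_low.predict(np.zeros((1, 2)))[0] == 0

    def test_score_is_mean_member_probability(self):
        est = self._vote([0.2, 0.4, 0.6, 0.8] * 2)
        assert est.predict_proba(np.zeros((1, 2)))[0, 1] == pytest.approx(0.5)


class TestStacking:
    def test_perfect_meta_features_give_training_auc_one(self):
        fm, y = separable_fm(20, seed=2)
        X = np.column_stack([y.astype(float), fm.data])
        members = [("oracle", FirstColumnStub())]
        est = StackingEnsembleClassifier(members=members, seed=0).fit(X, y)
        scores = est.predict_proba(X)[:, 1]
        assert ak.evaluate_predictions(y, scores).AUC == 1.0

    def test_out_of_fold_meta_features_are_leakage_free(self):
        fm, y = separable_fm(20, seed=8)
        members = [("memo", MemorizerStub())]
        est = StackingEnsembleClassifier(members=members, seed=3).fit(fm.data, y)
        # every meta-feature must come from folds that excluded the sample
        np.testing.assert_array_equal(est.oof_meta_features_, 0.5)
        assert sorted(np.unique(est.fold_assignments_)) == list(range(5))

    def test_separable_held_out_auc(self):
        fm, y = separable_fm(150, n_features=5, gap=2.5, seed=2)
        rng = np.random.default_rng(2)
        order = rng.permutation(300)
        train, test = order[:200], order[200:]
        est = StackingEnsembleClassifier(meta="lr", seed=2)
        est.fit(fm.data[train], y[train])
        scores = est.predict_proba(fm.data[test])[:, 1]
        assert ak.evaluate_predictions(y[test], scores).AUC >= 0.9

    def test_unknown_meta_raises(self):
        fm, y = separable_fm(20)
        with pytest.raises(ValueError, match="meta-learner"):
            StackingEnsembleClassifier(meta="rbf").fit(fm.data, y)

    def test_too_few_samples_per_class_raise(self):
        fm, y = separable_fm(8)
        with pytest.raises(ValueError, match="per class"):
            StackingEnsembleClassifier(meta="lr").fit(fm.data, y)

    def test_gbc_meta_fits(self):
        fm, y = separable_fm(20, seed=9)
        members = [("c", ConstantStub(0.5)), ("o", FirstColumnStub())]
        est = StackingEnsembleClassifier(meta="gbc", members=members, seed=0)
        est.fit(fm.data, y)
        assert est.predict(fm.data).shape == (40,)


class TestScoreAveraging:
    def test_idempotent_on_identical_tables(self):
        t = ScoreTable(["a", "b"], [0.3, 0.9], source="m1")
        avg = average_scores([t, ScoreTable(["a", "b"], [0.3, 0.9], source="m2")])
        np.testing.assert_allclose(avg.scores, t.scores)

    def test_arithmetic_mean(self):
        t1 = ScoreTable(["a"], [0.4])
        t2 = ScoreTable(["a"], [0.8])
        assert average_scores([t1, t2]).scores[0] == pytest.approx(0.6)

    def test_matches_loop_oracle(self, rng):
        ids = [f"r{i}" for i in range(30)]
        tables = [ScoreTable(ids, rng.random(30), source=str(k)) for k in range(3)]
        avg = average_scores(tables)
        for i in range(30):
            expected = sum(t.scores[i] for t in tables) / 3
            assert avg.scores[i] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError, match="identical records"):
            average_scores([ScoreTable(["a"], [0.1]), ScoreTable(["b"], [0.1])])

    def test_bounds_preserved(self, rng):
        ids = [f"r{i}" for i in range(10)]
        tables = [ScoreTable(ids, rng.random(10)) for _ in range(4)]
        avg = average_scores(tables)
        stackmat = np.vstack([t.scores for t in tables])
        assert np.all(avg.scores >= stackmat.min(axis=0) - 1e-12)
        assert np.all(avg.scores <= stackmat.max(axis=0) + 1e-12)


class TestCompositePredictor:
    def test_stubbed_submodel_score_algebra(self):
        fm, y = separable_fm(20, seed=4)
        blocks = [("b1", [0]), ("b2", [1]), ("b3", [0, 1])]
        est = FeatureAveragedClassifier(
            blocks=blocks,
            block_estimators={
                "b1": FirstColumnStub(),
                "b2": FirstColumnStub(),
                "b3": ConstantStub(0.5),
            },
        ).fit(fm.data, y)
        composite = est.predict_proba(fm.data)[:, 1]
        s1 = np.clip(fm.data[:, 0], 0, 1)
        s2 = np.clip(fm.data[:, 1], 0, 1)
        np.testing.assert_allclose(composite, (s1 + s2 + 0.5) / 3, atol=1e-12)

    def test_composite_not_much_worse_than_worst_submodel(self):
        fm, y = separable_fm(30, n_features=4, gap=2.0, seed=4)
        model = ak.train_composite(fm, fm, fm, y, seed=4)
        test_fm, test_y = separable_fm(25, n_features=4, gap=2.0, seed=14)
        stacked, _ = stack_feature_matrices([test_fm, test_fm, test_fm])
        composite_auc = ak.evaluate_predictions(
            test_y, ak.predict_scores(model, stacked).scores
        ).AUC
        sub_aucs = []
        for idx, sub in model.estimator.submodels_.values():
            scores = sub.predict_proba(stacked.data[:, idx])[:, 1]
            sub_aucs.append(ak.evaluate_predictions(test_y, scores).AUC)
        assert composite_auc >= min(sub_aucs) - 0.02

    def test_misaligned_row_ids_raise(self):
        fm1, y = separable_fm(10, seed=1)
        fm2, _ = separable_fm(10, seed=1)
        fm2 = FeatureMatrix([f"x{i}" for i in range(20)], fm2.data, fm2.columns)
        with pytest.raises(ValueError, match="row-aligned"):
            ak.train_composite(fm1, fm2, fm1, y)

    def test_schema_enforced_at_predict_time(self):
        fm, y = separable_fm(20, seed=6)
        model = ak.train_stacking(fm, y, meta="lr", seed=0,
                                  members=[("c", FirstColumnStub())])
        wrong = FeatureMatrix(fm.ids, fm.data, ["g0", "g1"])
        with pytest.raises(ValueError, match="schema"):
            ak.predict_scores(model, wrong)


class TestSeedDeterminism:
    @pytest.mark.parametrize("trainer", ["vote", "sta_lr", "sta_gbc"])
    def test_refit_scores_bit_identical(self, trainer):
        fm, y = separable_fm(15, n_features=3, gap=1.0, seed=5)
        members = ["svm", "mlp", "rf"]  # the members with internal randomness
        def fit():
            if trainer == "vote":
                return ak.train_vote(fm, y, seed=9, members=members)
            return ak.train_stacking(fm, y, meta=trainer.split("_")[1], seed=9,
                                     members=members)
        s1 = ak.predict_scores(fit(), fm).scores
        s2 = ak.predict_scores(fit(), fm).scores
        np.testing.assert_array_equal(s1, s2)
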