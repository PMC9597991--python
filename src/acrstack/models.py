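"""Base classifiers and ensemble combiners for anti-CRISPR prediction.

Eight base learners (SVM, KNN, MLP, LR, RF, XGBoost, LightGBM, and a
histogram gradient-boosted tree ensemble) sit behind one probabilistic
contract. Three combiners integrate them:

* hard voting ("ens_vote"): majority of 8 hard votes, mean member
  probability as the reported score, 4-4 ties resolved by that mean vs 0.5;
* stacking ("sta_lr" / "sta_gbc"): a logistic-regression or
  gradient-boosting meta-learner trained on the members' out-of-fold
  positive-class probabilities (5-fold, stratified, seeded), members
  refitted on the full data for deployment;
* feature averaging: the composite predictor trains one stacking model per
  feature block (PSSM autocovariance, reduced-PSSM descriptor, pooled
  embedding) and averages their scores.

All estimators follow the scikit-learn API and compose with its model
selection utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .records import FeatureMatrix

BASE_CLASSIFIERS = ("svm", "knn", "mlp", "lr", "rf", "xgb", "lgbm", "hgb")

# lightgbm 4.6's sklearn wrapper names features internally and then warns on
# every ndarray predict; the warning carries no information here.
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names, but LGBMClassifier"
)

_POW2_GRID = [2.0**e for e in range(-6, 7)]


def _grid_points(upper: int, max_points: int = 30) -> list[int]:
    """Integer grid 1..upper stepped down to at most ``max_points`` values."""
    upper = max(int(upper), 1)
    if upper <= max_points:
        return list(range(1, upper + 1))
    pts = np.unique(np.round(np.linspace(1, upper, max_points)).astype(int))
    return [int(v) for v in pts]


def _feanum_upper(n_features: int) -> int:
    """Search-space upper bound max(sqrt(FeaNum), FeaNum/2) on the feature count."""
    return int(max(np.sqrt(n_features), n_features / 2))


@dataclass
class ClassifierSpec:
    """Recipe for one base classifier: name, seed, and tuning switches."""

    name: str
    seed: int = 0
    tune: bool = False
    full_grid: bool = False
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASE_CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {BASE_CLASSIFIERS}"
            )


def make_base_classifier(spec: ClassifierSpec, n_features: int | None = None):
    """Build the (optionally grid-searched) estimator for a classifier spec.

    Grid spaces: SVM searches C and gamma over powers of two 2^-6..2^6; KNN
    searches k over 1..max(sqrt(FeaNum), FeaNum/2); RF searches the tree count
    over the same bound and mtry over {1, 6, 11, 16}. Integer grids are
    stepped to at most 30 points unless ``full_grid`` is set. Untuned
    estimators use fixed mid-grid settings. Grid search scores 5-fold CV
    accuracy on the training fold; ties go to the smallest parameter values.
    """
    name, seed = spec.name, spec.seed
    if name == "svm":
        # RBF SVM with Platt-style sigmoid calibration for probabilistic scores
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **spec.fixed),
            method="sigmoid",
            cv=5,
        )
        space = _POW2_GRID if spec.full_grid else _POW2_GRID[::3]
        grid = {"estimator__C": space, "estimator__gamma": space}
    elif name == "knn":
        est = KNeighborsClassifier(**{"n_neighbors": 5, **spec.fixed})
        upper = _feanum_upper(n_features) if n_features else 30
        grid = {
            "n_neighbors": _grid_points(upper, 1_000_000 if spec.full_grid else 30)
        }
    elif name == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=(64, 32), max_iter=1000, random_state=seed, **spec.fixed
        )
        grid = {}
    elif name == "lr":
        est = LogisticRegression(max_iter=1000, random_state=seed, **spec.fixed)
        grid = {}
    elif name == "rf":
        est = RandomForestClassifier(random_state=seed, **spec.fixed)
        upper = _feanum_upper(n_features) if n_features else 30
        mtry = [m for m in (1, 6, 11, 16) if n_features is None or m <= n_features]
        grid = {
            "n_estimators": _grid_points(upper, 1_000_000 if spec.full_grid else 30),
            "max_features": mtry or [1],
        }
    elif name == "xgb":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **spec.fixed,
        )
        grid = {}
    elif name == "lgbm":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **spec.fixed)
        grid = {}
    else:  # hgb
        est = HistGradientBoostingClassifier(random_state=seed, **spec.fixed)
        grid = {}

    if spec.tune and grid:
        return GridSearchCV(
            est,
            grid,
            scoring="accuracy",
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            n_jobs=1,
        )
    return est


def _check_two_classes(y: np.ndarray, min_per_class: int = 2) -> None:
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} samples per class, got {counts.min()}"
        )


class _EnsembleBase(ClassifierMixin, BaseEstimator):
    """Shared member handling for vote and stacking ensembles."""

    def _member_specs(self):
        members = self.members if self.members is not None else BASE_CLASSIFIERS
        out = []
        for m in members:
            if isinstance(m, str):
                out.append((m, None))
            else:  # (name, estimator) pair, e.g. a stub in tests
                out.append((m[0], m[1]))
        return out

    def _build_member(self, name, proto, n_features):
        if proto is not None:
            return clone(proto)
        return make_base_classifier(
            ClassifierSpec(name, seed=self.seed, tune=self.tune), n_features=n_features
        )

    def _positive_proba(self, est, X) -> np.ndarray:
        proba = est.predict_proba(X)
        return proba[:, list(est.classes_).index(1)]


class EnsembleVoteClassifier(_EnsembleBase):
    """Hard-voting ensemble over the eight base classifiers.

    The predicted label is the majority of the members' hard votes; the
    reported score is the mean of the members' positive-class probabilities,
    which also resolves even vote ties against 0.5.
    """

    def __init__(self, members=None, seed: int = 0, tune: bool = False):
        self.members = members
        self.seed = seed
        self.tune = tune

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y)
        self.classes_ = np.unique(y)
        self.members_ = {}
        for name, proto in self._member_specs():
            est = self._build_member(name, proto, X.shape[1])
            est.fit(X, y)
            self.members_[name] = est
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        p1 = np.mean(
            [self._positive_proba(est, X) for est in self.members_.values()], axis=0
        )
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        check_is_fitted(self)
        Xv = validate_data(self, X, reset=False, dtype=float)
        votes = np.sum([est.predict(Xv) for est in self.members_.values()], axis=0)
        n = len(self.members_)
        mean_p1 = self.predict_proba(X)[:, 1]
        labels = np.where(votes * 2 > n, 1, 0)
        tie = votes * 2 == n
        labels[tie] = (mean_p1[tie] >= 0.5).astype(int)
        return labels


class StackingEnsembleClassifier(_EnsembleBase):
    """Stacking ensemble: meta-learner over out-of-fold member probabilities.

    Meta-features for sample i come from members fitted on folds that exclude
    i (stratified 5-fold, shuffled from ``seed``), preventing leakage; the
    members are then refitted on the full data for deployment. ``meta`` is
    "lr" (logistic regression) or "gbc" (gradient boosting).
    """

    def __init__(
        self,
        meta: str = "lr",
        members=None,
        seed: int = 0,
        n_folds: int = 5,
        tune: bool = False,
    ):
        self.meta = meta
        self.members = members
        self.seed = seed
        self.n_folds = n_folds
        self.tune = tune

    def _make_meta(self):
        if self.meta == "lr":
            return LogisticRegression(max_iter=1000, random_state=self.seed)
        if self.meta == "gbc":
            return GradientBoostingClassifier(random_state=self.seed)
        raise ValueError(f"unknown meta-learner {self.meta!r}; choose 'lr' or 'gbc'")

    def fit(self, X, y):
        meta_est = self._make_meta()  # validate meta name before any work
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y, min_per_class=self.n_folds * 2)
        self.classes_ = np.unique(y)
        specs = self._member_specs()

        skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.seed)
        n = X.shape[0]
        oof = np.zeros((n, len(specs)))
        fold_of = np.full(n, -1, dtype=int)
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            fold_of[test_idx] = fold
            for col, (name, proto) in enumerate(specs):
                est = self._build_member(name, proto, X.shape[1])
                est.fit(X[train_idx], y[train_idx])
                oof[test_idx, col] = self._positive_proba(est, X[test_idx])

        self.meta_ = meta_est.fit(oof, y)
        self.oof_meta_features_ = oof
        self.fold_assignments_ = fold_of

        self.members_ = {}
        for name, proto in specs:
            est = self._build_member(name, proto, X.shape[1])
            est.fit(X, y)
            self.members_[name] = est
        return self

    def _meta_features(self, X) -> np.ndarray:
        return np.column_stack(
            [self._positive_proba(est, X) for est in self.members_.values()]
        )

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        p1 = self._positive_proba(self.meta_, self._meta_features(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class FeatureAveragedClassifier(ClassifierMixin, BaseEstimator):
    """Score-averaging composite over per-feature-block sub-models.

    ``blocks`` maps block names to column indices of the (concatenated) input
    matrix; one sub-model (by default a stacking ensemble with a logistic-
    regression meta-learner) is fitted per block and the composite score is
    the arithmetic mean of the blocks' positive-class probabilities. With the
    three evolutionary/embedding blocks this is the final composite predictor.
    """

    def __init__(
        self,
        blocks=None,
        meta: str = "lr",
        members=None,
        seed: int = 0,
        tune: bool = False,
        block_estimators: dict | None = None,
    ):
        self.blocks = blocks
        self.meta = meta
        self.members = members
        self.seed = seed
        self.tune = tune
        self.block_estimators = block_estimators

    def _block_items(self, n_features):
        if self.blocks is None:
            return [("all", np.arange(n_features))]
        return [(name, np.asarray(idx, dtype=int)) for name, idx in self.blocks]

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.submodels_ = {}
        for name, idx in self._block_items(X.shape[1]):
            if self.block_estimators and name in self.block_estimators:
                est = clone(self.block_estimators[name])
            else:
                est = StackingEnsembleClassifier(
                    meta=self.meta, members=self.members, seed=self.seed, tune=self.tune
                )
            self.submodels_[name] = (idx, est.fit(X[:, idx], y))
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        parts = []
        for idx, est in self.submodels_.values():
            proba = est.predict_proba(X[:, idx])
            parts.append(proba[:, list(est.classes_).index(1)])
        p1 = np.mean(parts, axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Score tables and feature-matrix-level training wrappers


@dataclass
class ScoreTable:
    """Per-record positive-class probabilities from one model."""

    record_ids: list[str]
    scores: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.record_ids) != len(self.scores):
            raise ValueError("one score per record required")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def labels(self) -> np.ndarray:
        return (self.scores >= 0.5).astype(int)


def average_scores(tables: list[ScoreTable]) -> ScoreTable:
    """Element-wise mean of score tables over identical records in identical order."""
    if not tables:
        raise ValueError("no score tables to average")
    ids = tables[0].record_ids
    for t in tables[1:]:
        if t.record_ids != ids:
            raise ValueError("score tables must cover identical records in order")
    return ScoreTable(
        record_ids=list(ids),
        scores=np.mean([t.scores for t in tables], axis=0),
        source="&".join(t.source for t in tables),
    )


@dataclass
class EnsembleModel:
    """A fitted predictor plus its expected feature schema.

    kind is one of single / ens_vote / sta_lr / sta_gbc / feature_average /
    composite; ``feature_schema`` lists the column names the estimator expects
    (for the composite predictor, the concatenation of its blocks).
    """

    kind: str
    estimator: object
    feature_schema: list[str]
    source: str = ""


def _check_schema(model: EnsembleModel, fm: FeatureMatrix) -> None:
    if list(fm.columns) != list(model.feature_schema):
        raise ValueError(
            f"feature columns do not match the model schema "
            f"({len(fm.columns)} vs {len(model.feature_schema)} columns)"
        )


def stack_feature_matrices(fms: list[FeatureMatrix]) -> tuple[FeatureMatrix, list]:
    """Column-concatenate row-aligned feature matrices; returns (matrix, blocks)."""
    ids = fms[0].ids
    for fm in fms[1:]:
        if fm.ids != ids:
            raise ValueError("feature matrices must be row-aligned to the same records")
    names, offset, blocks = [], 0, []
    for i, fm in enumerate(fms):
        name = fm.encoder or f"block{i}"
        if name in names:
            name = f"{name}_{i}"
        names.append(name)
        blocks.append((name, np.arange(offset, offset + fm.shape[1])))
        offset += fm.shape[1]
    columns = [c for fm in fms for c in fm.columns]
    if len(set(columns)) != len(columns):  # qualify with block names
        columns = [
            f"{name}.{c}" for name, fm in zip(names, fms) for c in fm.columns
        ]
    data = np.hstack([fm.data for fm in fms])
    return FeatureMatrix(list(ids), data, columns), blocks


def train_base(spec: ClassifierSpec, fm: FeatureMatrix, labels) -> EnsembleModel:
    """Fit a single (optionally grid-searched) base classifier."""
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    est = make_base_classifier(spec, n_features=fm.shape[1])
    est.fit(fm.data, y)
    return EnsembleModel("single", est, list(fm.columns), source=spec.name)


def train_vote(fm: FeatureMatrix, labels, seed: int = 0, members=None,
               tune: bool = False) -> EnsembleModel:
    est = EnsembleVoteClassifier(members=members, seed=seed, tune=tune)
    est.fit(fm.data, np.asarray(labels, dtype=int))
    return EnsembleModel("ens_vote", est, list(fm.columns), source="ens_vote")


def train_stacking(fm: FeatureMatrix, labels, meta: str = "lr", seed: int = 0,
                   members=None, tune: bool = False) -> EnsembleModel:
    est = StackingEnsembleClassifier(meta=meta, members=members, seed=seed, tune=tune)
    est.fit(fm.data, np.asarray(labels, dtype=int))
    return EnsembleModel(f"sta_{meta}", est, list(fm.columns), source=f"sta_{meta}")


def train_feature_average(fms: list[FeatureMatrix], labels, meta: str = "lr",
                          seed: int = 0, members=None, tune: bool = False,
                          kind: str = "feature_average") -> EnsembleModel:
    """Fit one stacking sub-model per feature matrix; predict by score averaging."""
    stacked, blocks = stack_feature_matrices(fms)
    est = FeatureAveragedClassifier(
        blocks=blocks, meta=meta, members=members, seed=seed, tune=tune
    )
    est.fit(stacked.data, np.asarray(labels, dtype=int))
    source = "&".join(name for name, _ in blocks)
    return EnsembleModel(kind, est, list(stacked.columns), source=source)


def train_composite(pssm_ac_fm: FeatureMatrix, rpssm_fm: FeatureMatrix,
                  ssa_fm: FeatureMatrix, labels, seed: int = 0, members=None,
                  tune: bool = False) -> EnsembleModel:
    """The composite predictor: three stacking-LR sub-models (PSSM
    autocovariance, reduced-PSSM descriptor, pooled embedding), scores averaged."""
    model = train_feature_average(
        [pssm_ac_fm, rpssm_fm, ssa_fm], labels, meta="lr", seed=seed,
        members=members, tune=tune, kind="composite",
    )
    return model


def predict_scores(model: EnsembleModel, fm: FeatureMatrix | list[FeatureMatrix]) -> ScoreTable:
    """Positive-class probabilities of a fitted model on a feature matrix.

    The composite predictor also accepts the list of per-block matrices, which
    are concatenated after a row-alignment check.
    """
    if isinstance(fm, list):
        fm, _ = stack_feature_matrices(fm)
    _check_schema(model, fm)
    est = model.estimator
    proba = est.predict_proba(fm.data)
    p1 = proba[:, list(est.classes_).index(1)]
    return ScoreTable(list(fm.ids), p1, source=model.source or model.kind)
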