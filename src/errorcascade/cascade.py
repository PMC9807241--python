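"""Error-routed three-stage ensemble classifier.

Stage I fits Naive Bayes, KNN and a C4.5-family tree on a core subset of
the training data.  Their per-instance correctness on the remaining
*routing* subset builds two pairwise-true pools — pool A (NB and KNN both
correct) and pool B (KNN and tree both correct) — plus the false pool F of
routing instances captured by neither pair.  Stage II fits a random forest
on pool A and a RIPPER rule learner on pool B.  Stage III fits a
linear-kernel SVM on the routing instances stage II classifies correctly
united with pool F; that SVM alone produces final predictions.

All routing happens inside the training partition: stage I is fit on an
internal sub-split (default 60 % of the training data) and correctness is
measured on the other 40 %, so no evaluation instance ever reaches a
fitting step.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import RecordTable, smote_balance
from .lda import ScatterLDA
from .learners import (
    GaussianNBClassifier,
    KNeighborsVoteClassifier,
    RipperClassifier,
    make_learner,
    LearnerSpec,
)

STAGE1_NAMES = ("nb", "knn", "j48")


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """A deterministic train/evaluation index split."""

    train_indices: np.ndarray
    eval_indices: np.ndarray
    train_fraction: float
    stratified: bool
    seed: int


def split_train_eval(
    table: RecordTable,
    fraction: float = 0.70,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Split a table into training and evaluation partitions.

    ``|train| = round(fraction * n)``; stratification preserves per-class
    proportions within one record.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(round(fraction * table.n))
    if not 0 < n_train < table.n:
        raise ValueError("split would leave an empty partition")
    idx = np.arange(table.n)
    train_idx, eval_idx = train_test_split(
        idx,
        train_size=n_train,
        stratify=table.labels if stratified else None,
        random_state=seed,
    )
    return SplitPlan(
        np.sort(train_idx), np.sort(eval_idx), fraction, stratified, seed
    )


@dataclasses.dataclass(frozen=True)
class StagePartition:
    """Routing result: correctness flags and the three instance pools.

    ``pool_a`` and ``pool_b`` may overlap; ``pool_f`` is the routing
    instances in neither, so A | B and F cover the routing set exactly.
    Indices refer to positions in the routing set's own index base.
    """

    correctness: dict[str, np.ndarray]
    pool_a: np.ndarray
    pool_b: np.ndarray
    pool_f: np.ndarray
    routing_indices: np.ndarray

    def __post_init__(self) -> None:
        in_ab = np.union1d(self.pool_a, self.pool_b)
        if np.intersect1d(in_ab, self.pool_f).size:
            raise AssertionError("pool F overlaps a pairwise-true pool")
        cover = np.union1d(in_ab, self.pool_f)
        if not np.array_equal(cover, np.sort(self.routing_indices)):
            raise AssertionError("pools do not cover the routing set")


def route_stage1(
    learners: Mapping[str, object],
    routing_table: RecordTable,
    pair_a: tuple[str, str] = ("nb", "knn"),
    pair_b: tuple[str, str] = ("knn", "j48"),
    routing_indices: np.ndarray | None = None,
) -> StagePartition:
    """Build the stage partition from fitted stage-I learners.

    Correctness is each learner's prediction compared with the routing
    labels; pool A holds instances where both ``pair_a`` learners are
    correct, pool B likewise for ``pair_b``, and F the remainder.
    """
    if routing_table.n == 0:
        raise ValueError("routing table is empty")
    if routing_indices is None:
        routing_indices = np.arange(routing_table.n)
    correctness = {
        name: np.asarray(learners[name].predict(routing_table.features))
        == routing_table.labels
        for name in learners
    }
    ok_a = correctness[pair_a[0]] & correctness[pair_a[1]]
    ok_b = correctness[pair_b[0]] & correctness[pair_b[1]]
    pool_a = routing_indices[ok_a]
    pool_b = routing_indices[ok_b]
    pool_f = routing_indices[~(ok_a | ok_b)]
    return StagePartition(correctness, pool_a, pool_b, pool_f, routing_indices)


def fit_stage1(
    train_core: RecordTable,
    specs: Mapping[str, LearnerSpec] | None = None,
) -> dict[str, object]:
    """Fit the three stage-I learners (NB, KNN, J48) on the core subset."""
    if specs is None:
        specs = {
            "nb": LearnerSpec("NB"),
            "knn": LearnerSpec("KNN"),
            "j48": LearnerSpec("J48"),
        }
    if set(specs) != set(STAGE1_NAMES):
        raise ValueError(f"stage-I specs must name exactly {STAGE1_NAMES}")
    return {
        name: make_learner(spec).fit(train_core.features, train_core.labels)
        for name, spec in specs.items()
    }


class CascadeEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Three-stage error-routed ensemble as a scikit-learn classifier.

    Parameters
    ----------
    use_lda : bool
        Fit a scatter-matrix LDA on the training data and run every stage
        in the projected space (one axis for binary labels).
    n_components : int or None
        Retained LDA axes when ``use_lda``; None means C-1.
    stage1_fraction : float
        Share of the training data used to fit the stage-I learners; the
        rest is the routing set where correctness is measured.
    pair_a, pair_b : tuple of str
        The stage-I learner pairs whose joint correctness defines pools A
        and B ("nb", "knn", "j48").
    stage2_rule : {"union", "intersection"}
        Whether a routing instance enters the stage-III set when either
        stage-II learner classifies it correctly, or only when both do.
    smote : bool
        Oversample the minority class (SMOTE) on the stage-I fitting
        subset only.
    knn_k, rf_trees, svm_c : stage hyperparameters.
    stage1_overrides : optional mapping name -> estimator factory, used to
        substitute stage-I learners (e.g. constant stubs in diagnostics).
    random_state : master seed fanned out to every stochastic step.

    Attributes
    ----------
    classes_ : array [0, 1]
    stage1_ : dict of the three fitted stage-I learners
    stage2_ : dict with the fitted "rf" and "jrip" learners (absent if its
        pool was empty)
    stage3_ : the fitted linear SVM producing final predictions
    partition_ : :class:`StagePartition` over the routing subset
    stage3_training_indices_ : indices (into the fit data) of the stage-III
        training set
    lda_ : fitted :class:`~errorcascade.lda.ScatterLDA` when enabled
    """

    def __init__(
        self,
        use_lda: bool = True,
        n_components: int | None = None,
        stage1_fraction: float = 0.6,
        pair_a: tuple[str, str] = ("nb", "knn"),
        pair_b: tuple[str, str] = ("knn", "j48"),
        stage2_rule: str = "union",
        smote: bool = False,
        smote_k: int = 5,
        knn_k: int = 5,
        rf_trees: int = 100,
        svm_c: float = 1.0,
        stage1_overrides: Mapping[str, Callable[[], object]] | None = None,
        random_state: int | None = None,
    ):
        self.use_lda = use_lda
        self.n_components = n_components
        self.stage1_fraction = stage1_fraction
        self.pair_a = pair_a
        self.pair_b = pair_b
        self.stage2_rule = stage2_rule
        self.smote = smote
        self.smote_k = smote_k
        self.knn_k = knn_k
        self.rf_trees = rf_trees
        self.svm_c = svm_c
        self.stage1_overrides = stage1_overrides
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _seeds(self) -> dict[str, int]:
        base = 0 if self.random_state is None else int(self.random_state)
        return {
            "split": base,
            "smote": base + 1,
            "rf": base + 2,
            "jrip": base + 3,
            "svm": base + 4,
        }

    def _make_stage1(self, seeds) -> dict[str, object]:
        builders: dict[str, Callable[[], object]] = {
            "nb": GaussianNBClassifier,
            "knn": lambda: KNeighborsVoteClassifier(n_neighbors=self.knn_k),
            "j48": lambda: make_learner(LearnerSpec("J48", seed=seeds["split"])),
        }
        if self.stage1_overrides:
            builders.update(self.stage1_overrides)
        return {name: builders[name]() for name in STAGE1_NAMES}

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("cascade requires exactly two classes")
        if self.stage2_rule not in ("union", "intersection"):
            raise ValueError("stage2_rule must be 'union' or 'intersection'")
        for name in (*self.pair_a, *self.pair_b):
            if name not in STAGE1_NAMES:
                raise ValueError(f"unknown stage-I learner {name!r} in pair")
        seeds = self._seeds()
        self.n_features_in_ = X.shape[1]

        # representation shared by every stage
        if self.use_lda:
            self.lda_ = ScatterLDA(n_components=self.n_components).fit(X, y)
            Xt = self.lda_.transform(X)
        else:
            self.lda_ = None
            Xt = X

        # internal sub-split: stage-I core vs routing set
        feature_names = tuple(f"z{j}" for j in range(Xt.shape[1]))
        table = RecordTable(Xt, y, feature_names)
        plan = split_train_eval(
            table,
            fraction=self.stage1_fraction,
            stratified=True,
            seed=seeds["split"],
        )
        core_idx, route_idx = plan.train_indices, plan.eval_indices
        core = table.take(core_idx)
        if self.smote:
            core = smote_balance(
                core, k_neighbors=self.smote_k, seed=seeds["smote"]
            ).table

        # stage I: fit and measure correctness on the routing set
        self.stage1_ = {
            name: est.fit(core.features, core.labels)
            for name, est in self._make_stage1(seeds).items()
        }
        routing = table.take(route_idx)
        self.partition_ = route_stage1(
            self.stage1_, routing, self.pair_a, self.pair_b, route_idx
        )

        # stage II: RF on pool A, RIPPER rules on pool B
        self.stage2_ = {}
        for name, pool, est in (
            (
                "rf",
                self.partition_.pool_a,
                make_learner(
                    LearnerSpec(
                        "RF", {"n_trees": self.rf_trees}, seed=seeds["rf"]
                    )
                ),
            ),
            (
                "jrip",
                self.partition_.pool_b,
                RipperClassifier(random_state=seeds["jrip"]),
            ),
        ):
            if pool.size == 0:
                warnings.warn(
                    f"stage-II pool for {name!r} is empty; learner skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            self.stage2_[name] = est.fit(Xt[pool], y[pool])

        # stage III training set: stage-II-correct routing instances + pool F
        correct_sets = [
            route_idx[np.asarray(est.predict(Xt[route_idx])) == y[route_idx]]
            for est in self.stage2_.values()
        ]
        if not correct_sets:
            stage2_correct = np.array([], dtype=int)
        elif self.stage2_rule == "union":
            stage2_correct = np.union1d(*correct_sets) if len(
                correct_sets
            ) > 1 else correct_sets[0]
        else:
            stage2_correct = np.intersect1d(*correct_sets) if len(
                correct_sets
            ) > 1 else correct_sets[0]
        stage3_idx = np.union1d(stage2_correct, self.partition_.pool_f).astype(
            int
        )
        if stage3_idx.size == 0:
            raise ValueError("stage-III training set is empty")
        if len(np.unique(y[stage3_idx])) < 2:
            raise ValueError(
                "stage-III training set collapsed to a single class"
            )
        self.stage3_training_indices_ = stage3_idx
        self.stage3_ = SVC(
            kernel="linear", C=self.svm_c, random_state=seeds["svm"]
        ).fit(Xt[stage3_idx], y[stage3_idx])
        return self

    # ------------------------------------------------------------------

    def _transform(self, X):
        check_is_fitted(self, "stage3_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.lda_.transform(X) if self.lda_ is not None else X

    def predict(self, X):
        """Final predictions: the stored stage-III SVM on the shared representation."""
        return self.stage3_.predict(self._transform(X))

    def decision_function(self, X):
        """Signed margin of the stage-III SVM (positive favours class 1)."""
        return self.stage3_.decision_function(self._transform(X))


@dataclasses.dataclass(frozen=True)
class CascadeModel:
    """A fitted cascade plus the split plan it was trained under."""

    classifier: CascadeEnsembleClassifier
    plan: SplitPlan
    config: dict


def fit_cascade(table: RecordTable, config: dict | None = None) -> CascadeModel:
    """Protocol wrapper: 70/30 split, fit the cascade on the training side.

    ``config`` keys (all optional): ``train_fraction`` (default 0.70),
    ``seed``, and any :class:`CascadeEnsembleClassifier` constructor
    parameter.
    """
    config = dict(config or {})
    fraction = config.pop("train_fraction", 0.70)
    seed = config.pop("seed", 0)
    plan = split_train_eval(table, fraction=fraction, stratified=True, seed=seed)
    clf = CascadeEnsembleClassifier(random_state=seed, **config)
    train = table.take(plan.train_indices)
    clf.fit(train.features, train.labels)
    return CascadeModel(clf, plan, {"train_fraction": fraction, "seed": seed, **config})


def predict_cascade(model: CascadeModel | CascadeEnsembleClassifier, features):
    clf = model.classifier if isinstance(model, CascadeModel) else model
    return clf.predict(np.asarray(features, float))
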