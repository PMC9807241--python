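"""The six base classifiers under one fit/predict/score contract.

Naive Bayes (Gaussian class-conditionals), k-nearest-neighbour voting and
the information-gain split statistic are implemented natively.  The C4.5
family tree ("J48"), random forest and linear-kernel SVM are backed by
scikit-learn estimators that conform to the same contract; the RIPPER-style
ordered rule learner ("JRip") is implemented here with IREP grow/prune
reduced-error pruning.

Every learner exposes ``predict`` returning hard 0/1 labels and a positive
score (``predict_proba[:, 1]`` or ``decision_function``) monotone in
positive-class confidence, which is what the AUC computation consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import RecordTable

LEARNER_KINDS = ("NB", "KNN", "J48", "JRip", "RF", "SVM")

#: hard upper bound on the neighbourhood size, k <= 20
KNN_MAX_K = 20


@dataclasses.dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of one base learner."""

    kind: str
    hyperparams: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(
                f"unknown learner kind {self.kind!r}; expected one of {LEARNER_KINDS}"
            )
        if self.kind == "KNN":
            k = self.hyperparams.get("k", 5)
            if not (isinstance(k, (int, np.integer)) and 1 <= k <= KNN_MAX_K):
                raise ValueError(f"KNN k must be a positive integer <= {KNN_MAX_K}")
        if self.kind == "SVM":
            kernel = self.hyperparams.get("kernel", "linear")
            if kernel != "linear":
                raise ValueError("SVM kernel is fixed to linear")


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class NBModel:
    """Fitted naive-Bayes parameters: priors and per-class Gaussians."""

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # (C, d)
    variances: np.ndarray  # (C, d), floored


class GaussianNBClassifier(BaseEstimator, ClassifierMixin):
    """Naive Bayes with Gaussian class-conditional likelihoods.

    The posterior is Bayes' rule, likelihood x class prior / evidence,
    evaluated in log space and renormalised.  Per-class per-feature
    variances are floored at ``var_floor_rel`` times the largest feature
    variance so constant features never divide by zero.
    """

    def __init__(self, var_floor_rel: float = 1e-9):
        self.var_floor_rel = var_floor_rel

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        counts = np.array([(y == c).sum() for c in self.classes_])
        if (counts < 2).any():
            bad = self.classes_[counts < 2]
            raise ValueError(
                f"class {bad[0]} has fewer than 2 records; variance not estimable"
            )
        self.priors_ = counts / counts.sum()
        self.theta_ = np.vstack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        var = np.vstack([X[y == c].var(axis=0) for c in self.classes_])
        floor = self.var_floor_rel * max(X.var(axis=0).max(), 1.0)
        self.var_ = np.maximum(var, floor)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        X = check_array(X)
        jll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            diff = X - self.theta_[i]
            jll[:, i] = (
                np.log(self.priors_[i])
                - 0.5 * np.sum(np.log(2.0 * np.pi * self.var_[i]))
                - 0.5 * np.sum(diff**2 / self.var_[i], axis=1)
            )
        return jll

    def predict_proba(self, X):
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        post = np.exp(jll)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def model_(self) -> NBModel:
        check_is_fitted(self, "theta_")
        return NBModel(self.classes_, self.priors_, self.theta_, self.var_)


def fit_naive_bayes(features, labels) -> GaussianNBClassifier:
    return GaussianNBClassifier().fit(features, labels)


def nb_posterior(model: GaussianNBClassifier, x) -> np.ndarray:
    """Per-class posterior probabilities for a single query vector."""
    return model.predict_proba(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# k-nearest neighbours
# ---------------------------------------------------------------------------


class KNeighborsVoteClassifier(BaseEstimator, ClassifierMixin):
    """Majority vote over the k Euclidean-nearest training records.

    Vote ties are broken by the smaller summed distance of the tied
    label's members within the neighbourhood, then by the smaller label.
    The positive score is the positive-class vote fraction.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 1 <= self.n_neighbors <= min(KNN_MAX_K, X.shape[0]):
            raise ValueError(
                f"n_neighbors must be in [1, min({KNN_MAX_K}, n_train)]"
            )
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _neighbours(self, X):
        dist = cdist(X, self.X_)
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.n_neighbors]
        return order, np.take_along_axis(dist, order, axis=1)

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X)
        order, dist = self._neighbours(X)
        out = np.empty(X.shape[0], dtype=self.y_.dtype)
        for i in range(X.shape[0]):
            labels = self.y_[order[i]]
            cands = np.unique(labels)
            counts = np.array([(labels == c).sum() for c in cands])
            sums = np.array([dist[i][labels == c].sum() for c in cands])
            # lexicographic: most votes, then smaller summed distance,
            # then smaller label
            best = min(
                range(len(cands)),
                key=lambda j: (-counts[j], sums[j], cands[j]),
            )
            out[i] = cands[best]
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X)
        order, _ = self._neighbours(X)
        proba = np.empty((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            proba[:, j] = (self.y_[order] == c).mean(axis=1)
        return proba


def knn_predict(train: RecordTable, x, k: int):
    """Label of a single query under the k-NN vote rule."""
    clf = KNeighborsVoteClassifier(n_neighbors=k).fit(
        train.features, train.labels
    )
    return clf.predict(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# information gain
# ---------------------------------------------------------------------------


def _entropy_bits(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(labels, partition) -> float:
    """Entropy reduction (bits) of a branch assignment over the records.

    ``partition`` assigns every record to a branch; the gain is
    H(labels) minus the branch-size-weighted mean of branch entropies.
    """
    labels = np.asarray(labels)
    partition = np.asarray(partition)
    if labels.size == 0:
        raise ValueError("empty partition")
    if partition.shape != labels.shape:
        raise ValueError("partition must assign every record to a branch")
    gain = _entropy_bits(labels)
    for b in np.unique(partition):
        mask = partition == b
        gain -= mask.mean() * _entropy_bits(labels[mask])
    return gain


# ---------------------------------------------------------------------------
# RIPPER-style ordered rule induction
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Rule:
    """Conjunction of numeric threshold conditions predicting the positive class."""

    conditions: tuple[tuple[int, str, float], ...]  # (feature, '<='|'>=', thr)
    laplace: float = 0.5  # training precision estimate, used as score

    def covers(self, X: np.ndarray) -> np.ndarray:
        mask = np.ones(X.shape[0], dtype=bool)
        for j, op, thr in self.conditions:
            col = X[:, j]
            mask &= (col <= thr) if op == "<=" else (col >= thr)
        return mask


class RipperClassifier(BaseEstimator, ClassifierMixin):
    """Ordered rule list grown for the minority class with reduced-error pruning.

    Each iteration splits the not-yet-covered training data into a growing
    set (2/3) and a pruning set (1/3); a rule is grown condition-by-condition
    maximising FOIL information gain until it covers no growing-set
    negatives, then pruned back to the condition prefix maximising
    (p - n) / (p + n) on the pruning set.  Rule induction stops when the
    pruned rule is no better than chance on the pruning set.  Uncovered
    instances get the default (majority) class.
    """

    def __init__(
        self,
        max_rules: int = 32,
        max_conditions: int = 8,
        max_thresholds: int = 24,
        random_state: int | None = None,
    ):
        self.max_rules = max_rules
        self.max_conditions = max_conditions
        self.max_thresholds = max_thresholds
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------

    def _candidate_conditions(self, X: np.ndarray):
        cands = []
        for j in range(X.shape[1]):
            vals = np.unique(X[:, j])
            if len(vals) < 2:
                continue
            mids = (vals[:-1] + vals[1:]) / 2.0
            if len(mids) > self.max_thresholds:
                idx = np.linspace(0, len(mids) - 1, self.max_thresholds)
                mids = mids[idx.astype(int)]
            for thr in mids:
                cands.append((j, "<=", float(thr)))
                cands.append((j, ">=", float(thr)))
        return cands

    @staticmethod
    def _foil_gain(p0, n0, p1, n1) -> float:
        if p1 == 0:
            return -np.inf
        before = np.log2(p0 / (p0 + n0)) if p0 > 0 else -np.inf
        after = np.log2(p1 / (p1 + n1))
        return p1 * (after - before)

    def _grow(self, X, y_pos):
        conds: list[tuple[int, str, float]] = []
        mask = np.ones(X.shape[0], dtype=bool)
        cands = self._candidate_conditions(X)
        while len(conds) < self.max_conditions:
            p0 = int(y_pos[mask].sum())
            n0 = int((~y_pos[mask]).sum())
            if n0 == 0:
                break
            best, best_gain = None, 0.0
            for j, op, thr in cands:
                col = X[:, j]
                new = mask & ((col <= thr) if op == "<=" else (col >= thr))
                p1 = int(y_pos[new].sum())
                n1 = int((~y_pos[new]).sum())
                gain = self._foil_gain(p0, n0, p1, n1)
                if gain > best_gain + 1e-12:
                    best, best_gain = (j, op, thr, new), gain
            if best is None:
                break
            j, op, thr, mask = best
            conds.append((j, op, thr))
        return conds

    @staticmethod
    def _prune_value(conds, X, y_pos):
        mask = Rule(tuple(conds)).covers(X)
        p = int(y_pos[mask].sum())
        n = int((~y_pos[mask]).sum())
        if p + n == 0:
            return -np.inf, p, n
        return (p - n) / (p + n), p, n

    def _prune(self, conds, X, y_pos):
        best_len, best_val = len(conds), -np.inf
        for keep in range(1, len(conds) + 1):
            val, _, _ = self._prune_value(conds[:keep], X, y_pos)
            if val > best_val + 1e-12:
                best_len, best_val = keep, val
        return conds[:best_len]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        if len(self.classes_) == 1:
            # constant predictor on degenerate (e.g. routed) pools
            self.positive_class_ = self.classes_[0]
            self.default_class_ = self.classes_[0]
            self.rules_ = []
            self.default_score_ = 1.0 if self.classes_[0] == 1 else 0.0
            return self
        counts = np.array([(y == c).sum() for c in self.classes_])
        # grow rules for the minority class; ties favour the higher label
        self.positive_class_ = self.classes_[
            np.lexsort((-self.classes_, counts))[0]
        ]
        self.default_class_ = self.classes_[
            self.classes_ != self.positive_class_
        ][0]
        rng = np.random.default_rng(self.random_state)
        y_pos = y == self.positive_class_
        remaining = np.arange(X.shape[0])
        rules: list[Rule] = []
        while (
            y_pos[remaining].sum() > 0
            and len(rules) < self.max_rules
        ):
            perm = rng.permutation(remaining)
            n_grow = max(int(np.ceil(2 * len(perm) / 3)), 1)
            grow_idx, prune_idx = perm[:n_grow], perm[n_grow:]
            if y_pos[grow_idx].sum() == 0:
                break
            conds = self._grow(X[grow_idx], y_pos[grow_idx])
            if not conds:
                break
            if len(prune_idx) > 0 and y_pos[prune_idx].sum() > 0:
                conds = self._prune(conds, X[prune_idx], y_pos[prune_idx])
                _, p, n = self._prune_value(conds, X[prune_idx], y_pos[prune_idx])
                if p + n > 0 and p / (p + n) < 0.5:
                    break
            rule = Rule(tuple(conds))
            covered = rule.covers(X[remaining])
            if covered.sum() == 0:
                break
            # Laplace-smoothed precision on the full training set = score
            full = rule.covers(X)
            laplace = (y_pos[full].sum() + 1) / (full.sum() + 2)
            rules.append(Rule(rule.conditions, float(laplace)))
            remaining = remaining[~covered]
        self.rules_ = rules
        self.default_score_ = float(
            (y_pos[remaining].sum() + 1) / (len(remaining) + 2)
        )
        return self

    def _positive_proba(self, X):
        score = np.full(X.shape[0], self.default_score_)
        unassigned = np.ones(X.shape[0], dtype=bool)
        for rule in self.rules_:
            hit = rule.covers(X) & unassigned
            score[hit] = rule.laplace
            unassigned &= ~hit
        return score

    def predict_proba(self, X):
        check_is_fitted(self, "rules_")
        X = check_array(X)
        p_pos = self._positive_proba(X)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            proba[:, j] = p_pos if c == self.positive_class_ else 1.0 - p_pos
        if len(self.classes_) == 1:
            proba[:] = 1.0
        return proba

    def predict(self, X):
        check_is_fitted(self, "rules_")
        X = check_array(X)
        covered = np.zeros(X.shape[0], dtype=bool)
        for rule in self.rules_:
            covered |= rule.covers(X)
        return np.where(covered, self.positive_class_, self.default_class_)


# ---------------------------------------------------------------------------
# uniform factory and scoring
# ---------------------------------------------------------------------------


def fit_learner(spec: LearnerSpec, features, labels):
    """Fit the learner a :class:`LearnerSpec` describes; uniform contract."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    est = make_learner(spec)
    return est.fit(features, labels)


def make_learner(spec: LearnerSpec):
    """Instantiate an unfitted estimator for a learner spec."""
    h = spec.hyperparams
    if spec.kind == "NB":
        return GaussianNBClassifier(var_floor_rel=h.get("var_floor_rel", 1e-9))
    if spec.kind == "KNN":
        return KNeighborsVoteClassifier(n_neighbors=h.get("k", 5))
    if spec.kind == "J48":
        return DecisionTreeClassifier(
            criterion="entropy",
            max_depth=h.get("max_depth"),
            min_samples_leaf=h.get("min_samples_leaf", 1),
            random_state=spec.seed,
        )
    if spec.kind == "JRip":
        return RipperClassifier(random_state=spec.seed)
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=h.get("n_trees", 100),
            max_depth=h.get("max_depth"),
            bootstrap=h.get("bootstrap", True),
            random_state=spec.seed,
        )
    if spec.kind == "SVM":
        return SVC(kernel="linear", C=h.get("C", 1.0), random_state=spec.seed)
    raise ValueError(f"unknown learner kind {spec.kind!r}")


def positive_score(model, X) -> np.ndarray:
    """A score monotone in positive-class confidence, for ROC/AUC.

    Probabilistic learners report P(class 1); margin learners report the
    signed decision value for class 1.
    """
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        classes = list(model.classes_)
        return proba[:, classes.index(1)] if 1 in classes else 1.0 - proba[:, 0]
    return np.asarray(model.decision_function(X), float)
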