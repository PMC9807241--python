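"""Linear discriminant analysis built from scatter matrices.

The transform is computed in five phases: per-class mean vectors; the
within-class scatter S_W = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)' and
between-class scatter S_B = sum_c n_c (mu_c - mu)(mu_c - mu)'; the
eigendecomposition of S_W^-1 S_B; selection of the top-m eigenvectors into
a d x m projection matrix w; and the projection Z = X w.  For C classes at
most C-1 eigenvalues are non-zero, so a binary problem yields a single
discriminant axis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import RecordTable

#: relative tolerance below which an eigenvalue counts as zero rank
EIG_TOL = 1e-8
#: relative pseudo-inverse cutoff for rank-deficient S_W
PINV_RCOND = 1e-10


def class_means(
    features: np.ndarray, labels: np.ndarray
) -> dict[int, np.ndarray]:
    """Arithmetic mean vector of each class (phase 1)."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    means = {}
    for c in np.unique(labels):
        rows = features[labels == c]
        if rows.shape[0] == 0:
            raise ValueError(f"class {c} has no records")
        means[int(c)] = rows.mean(axis=0)
    return means


def scatter_matrices(
    features: np.ndarray,
    labels: np.ndarray,
    means: dict[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter matrices (phase 2)."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    if means is None:
        means = class_means(features, labels)
    d = features.shape[1]
    grand = features.mean(axis=0)
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for c, mu in means.items():
        mu = np.asarray(mu, float)
        if mu.shape != (d,):
            raise ValueError("class mean dimension mismatch")
        rows = features[labels == c]
        centred = rows - mu
        s_w += centred.T @ centred
        diff = (mu - grand)[:, None]
        s_b += rows.shape[0] * (diff @ diff.T)
    return s_w, s_b


def solve_discriminants(
    s_w: np.ndarray, s_b: np.ndarray, tol: float = EIG_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted eigenpairs of S_W^-1 S_B (phases 3-4).

    Returns eigenvalues in descending order and unit-norm eigenvectors as
    columns, sign-fixed so the first non-zero coordinate of each vector is
    positive.  A numerically singular S_W falls back to the Moore-Penrose
    pseudo-inverse with a warning.
    """
    s_w = np.asarray(s_w, float)
    s_b = np.asarray(s_b, float)
    if s_w.shape != s_b.shape or s_w.shape[0] != s_w.shape[1]:
        raise ValueError("scatter matrices must be square and same shape")
    d = s_w.shape[0]
    rank = np.linalg.matrix_rank(s_w, tol=PINV_RCOND * np.linalg.norm(s_w, 2))
    if rank < d:
        warnings.warn(
            "within-class scatter is singular; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        inv = np.linalg.pinv(s_w, rcond=PINV_RCOND)
    else:
        inv = np.linalg.inv(s_w)
    eigvals, eigvecs = scipy.linalg.eig(inv @ s_b)
    eigvals = eigvals.real
    eigvecs = eigvecs.real
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    norms = np.linalg.norm(eigvecs, axis=0)
    norms[norms == 0] = 1.0
    eigvecs = eigvecs / norms
    for j in range(eigvecs.shape[1]):
        col = eigvecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            eigvecs[:, j] = -col
    return eigvals, eigvecs


def project(features: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Phase 5: the plain matrix product Z = X w (no extra centring)."""
    features = np.asarray(features, float)
    w = np.asarray(w, float)
    if features.shape[1] != w.shape[0]:
        raise ValueError(
            f"cannot project {features.shape} through {w.shape}: "
            "inner dimensions disagree"
        )
    return features @ w


@dataclasses.dataclass(frozen=True)
class LDAProjection:
    """Frozen result of an LDA fit: all five phases' intermediates."""

    class_means: dict[int, np.ndarray]
    s_w: np.ndarray
    s_b: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    w: np.ndarray
    m: int


class ScatterLDA(BaseEstimator, TransformerMixin):
    """LDA dimensionality reduction as a scikit-learn transformer.

    Parameters
    ----------
    n_components : int or None
        Retained discriminant axes m; defaults to C-1 (1 for binary
        problems), the rank bound of the between-class scatter.

    Attributes
    ----------
    projection_ : LDAProjection with means, scatters, eigenpairs and w.
    components_ : (d, m) projection matrix, unit-norm columns.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        max_m = min(X.shape[1], len(classes) - 1)
        m = max_m if self.n_components is None else int(self.n_components)
        if not 1 <= m <= max_m:
            raise ValueError(
                f"n_components must be in [1, {max_m}] for "
                f"{len(classes)} classes and {X.shape[1]} features"
            )
        means = class_means(X, y)
        s_w, s_b = scatter_matrices(X, y, means)
        eigvals, eigvecs = solve_discriminants(s_w, s_b)
        w = eigvecs[:, :m]
        self.projection_ = LDAProjection(
            class_means=means,
            s_w=s_w,
            s_b=s_b,
            eigenvalues=eigvals,
            eigenvectors=eigvecs,
            w=w,
            m=m,
        )
        self.components_ = w
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X)
        return project(X, self.components_)


def fit_lda(table: RecordTable, m: int | None = None) -> ScatterLDA:
    """Fit :class:`ScatterLDA` on a RecordTable."""
    return ScatterLDA(n_components=m).fit(table.features, table.labels)


def fisher_criterion(
    direction: np.ndarray, s_w: np.ndarray, s_b: np.ndarray
) -> float:
    """Generalised Rayleigh quotient a'S_B a / a'S_W a for a direction a."""
    a = np.asarray(direction, float)
    denom = a @ s_w @ a
    if denom <= 0:
        raise ValueError("direction lies in the null space of S_W")
    return float((a @ s_b @ a) / denom)
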