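"""Synthetic generator for Pima-like tabular classification data.

Draws labels Bernoulli(class_prior) and features from class-conditional
Gaussians with a shared covariance, then zero-inflates selected columns to
emulate the missing-value-coded zeros of the reference dataset.  Shared
covariance makes the Bayes-optimal rule linear, so the closed-form Bayes
error is available as ground truth for accuracy checks, and the optimal
discriminant direction is cov^-1 (mu1 - mu0).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .data import DEFAULT_ZERO_FEATURES, PIMA_FEATURES, RecordTable


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class shared-covariance Gaussian generator."""

    n: int
    class_prior: float
    mean_0: np.ndarray
    mean_1: np.ndarray
    cov: np.ndarray
    feature_names: tuple[str, ...] = PIMA_FEATURES
    zero_inflation: Mapping[str, float] = dataclasses.field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_0", np.asarray(self.mean_0, float))
        object.__setattr__(self, "mean_1", np.asarray(self.mean_1, float))
        object.__setattr__(self, "cov", np.asarray(self.cov, float))
        if not 0.0 < self.class_prior < 1.0:
            raise ValueError("class_prior must be in (0, 1)")
        d = len(self.feature_names)
        if self.mean_0.shape != (d,) or self.mean_1.shape != (d,):
            raise ValueError("mean vectors must have length d")
        if self.cov.shape != (d, d):
            raise ValueError("cov must be d x d")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ValueError("cov must be positive definite")
        for name, p in self.zero_inflation.items():
            if name not in self.feature_names:
                raise ValueError(f"unknown zero-inflated feature {name!r}")
            if not 0.0 <= p < 1.0:
                raise ValueError("zero-inflation probabilities must be in [0, 1)")

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def mahalanobis_delta(self) -> float:
        """Mahalanobis distance between the class means under the shared cov."""
        diff = self.mean_1 - self.mean_0
        return float(np.sqrt(diff @ np.linalg.solve(self.cov, diff)))


# Typical locations and spreads of the eight reference features for the
# healthy class (pregnancies, glucose, blood pressure, skin thickness,
# insulin, BMI, pedigree, age).  The diseased class is shifted along a
# clinically plausible direction (higher glucose, BMI, age, pregnancies),
# rescaled to reach a requested Mahalanobis separation.
_BASE_MEAN = np.array([3.0, 110.0, 70.0, 27.0, 100.0, 31.0, 0.43, 31.0])
_BASE_SD = np.array([3.0, 25.0, 12.0, 10.0, 85.0, 6.5, 0.30, 11.0])
_SHIFT_DIRECTION = np.array([0.6, 30.0, 4.0, 3.0, 60.0, 4.5, 0.12, 6.0])


def pima_like_spec(
    n: int = 768,
    class_prior: float = 268 / 768,
    delta: float = 2.0,
    zero_inflation: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SyntheticSpec:
    """Build a spec emulating the reference diabetes dataset.

    Parameters
    ----------
    n : number of records (768 matches the reference dataset size).
    class_prior : probability of the positive (diseased) class; the
        reference imbalance is 268 positives out of 768.
    delta : Mahalanobis separation between the class means.  ``delta=2``
        gives a Bayes error of Phi(-1) ~ 0.159 at equal priors, a realistic
        difficulty for clinical tabular data.
    zero_inflation : per-feature probability of overwriting a cell with 0;
        defaults to 3 % on Glucose, BloodPressure and BMI so the cleaning
        stage has work to do.
    """
    if zero_inflation is None:
        zero_inflation = {name: 0.03 for name in DEFAULT_ZERO_FEATURES}
    cov = np.diag(_BASE_SD**2)
    # mild positive correlations between adiposity-linked features
    for i, j, r in [(3, 5, 0.4), (1, 4, 0.3), (0, 7, 0.5)]:
        cov[i, j] = cov[j, i] = r * _BASE_SD[i] * _BASE_SD[j]
    raw = _SHIFT_DIRECTION
    scale = delta / np.sqrt(raw @ np.linalg.solve(cov, raw))
    return SyntheticSpec(
        n=n,
        class_prior=class_prior,
        mean_0=_BASE_MEAN,
        mean_1=_BASE_MEAN + scale * raw,
        cov=cov,
        zero_inflation=dict(zero_inflation),
        seed=seed,
    )


def generate(spec: SyntheticSpec) -> RecordTable:
    """Draw a RecordTable from the generator; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.class_prior).astype(int)
    chol = np.linalg.cholesky(spec.cov)
    z = rng.standard_normal((spec.n, spec.d))
    means = np.where(labels[:, None] == 1, spec.mean_1, spec.mean_0)
    features = means + z @ chol.T
    for name, p in spec.zero_inflation.items():
        if p > 0:
            j = spec.feature_names.index(name)
            mask = rng.random(spec.n) < p
            features[mask, j] = 0.0
    return RecordTable(features, labels, spec.feature_names)


def bayes_error(spec: SyntheticSpec) -> float:
    """Optimal misclassification rate of the two-Gaussian mixture.

    Only defined for the clean generator (no zero inflation).  With
    Delta^2 = (mu1-mu0)' cov^-1 (mu1-mu0) the optimal rule thresholds the
    linear discriminant score, giving

        error = pi0 * Phi(-Delta/2 - c/Delta) + pi1 * Phi(-Delta/2 + c/Delta)

    with c = log(pi0/pi1); at equal priors this reduces to Phi(-Delta/2).
    """
    if any(p > 0 for p in spec.zero_inflation.values()):
        raise ValueError("bayes_error requires zero_inflation to be inactive")
    delta = spec.mahalanobis_delta()
    if delta == 0.0:
        return float(min(spec.class_prior, 1.0 - spec.class_prior))
    pi1 = spec.class_prior
    pi0 = 1.0 - pi1
    c = np.log(pi0 / pi1)
    return float(
        pi0 * norm.cdf(-delta / 2.0 - c / delta)
        + pi1 * norm.cdf(-delta / 2.0 + c / delta)
    )


def optimal_direction(spec: SyntheticSpec) -> np.ndarray:
    """Unit vector along cov^-1 (mu1 - mu0), the Bayes discriminant axis."""
    w = np.linalg.solve(spec.cov, spec.mean_1 - spec.mean_0)
    return w / np.linalg.norm(w)
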