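import numpy as np
import pytest

from errorcascade import RecordTable, generate, pima_like_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """5 records, 3 features, one zero-BMI row."""
    features = np.array(
        [
            [1.0, 95.0, 30.0],
            [2.0, 140.0, 0.0],
            [0.0, 110.0, 26.5],
            [4.0, 160.0, 35.2],
            [1.0, 88.0, 22.1],
        ]
    )
    labels = np.array([0, 1, 0, 1, 0])
    return RecordTable(features, labels, ("Pregnancies", "Glucose", "BMI"))


@pytest.fixture
def clean_gaussian_table():
    """Shared-covariance two-class sample without zero inflation."""
    spec = pima_like_spec(
        n=600, class_prior=0.5, delta=2.0, zero_inflation={}, seed=99
    )
    return generate(spec)
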