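import numpy as np
import pytest

from survpls.simulators import attach_survival, simulate_factorial
from survpls.survival_core import SurvivalOutcome


@pytest.fixture
def toy_outcome():
    """Three subjects, all events."""
    return SurvivalOutcome([1.0, 2.0, 3.0], [1, 1, 1])


@pytest.fixture
def two_subject_outcome():
    return SurvivalOutcome([1.0, 2.0], [1, 1])


@pytest.fixture
def random_survival():
    """Moderate random dataset with censoring (n=60, q=3)."""
    rng = np.random.default_rng(7)
    n = 60
    X = rng.standard_normal((n, 3))
    eta = X @ np.array([0.5, -0.3, 0.0])
    T = rng.exponential(np.exp(-eta))
    C = rng.exponential(1.5, size=n)
    outcome = SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))
    return X, outcome


@pytest.fixture(scope="session")
def factorial_linear_dataset():
    """One factorial-scheme dataset with a linear survival link (smallish p)."""
    X = simulate_factorial(n=100, p=200, seed=11)
    outcome = attach_survival(X, link="linear", seed=12)
    return X, outcome
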