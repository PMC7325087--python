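import numpy as np
import pytest

from shaplogit.data import LabeledDataset


class FunctionModel:
    """Duck-typed predictor wrapping an arbitrary f(X) -> scores.

    Used to probe the model-agnostic Shapley machinery with analytically
    tractable games (constant, additive, multiplicative).
    """

    is_tree_ensemble = False
    supports_probability = True

    def __init__(self, fn):
        self.fn = fn

    def predict_probability(self, X):
        return np.asarray(self.fn(np.atleast_2d(np.asarray(X, dtype=float))))

    def predict_label(self, X):
        return (self.predict_probability(X) > 0.5).astype(int)


@pytest.fixture
def function_model():
    return FunctionModel


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 3))
    y = (X[:, 0] + X[:, 1] * X[:, 2] + 0.2 * rng.normal(size=60) > 0).astype(int)
    return LabeledDataset(X, y, ("a", "b", "c"))


def random_tree_fixture(rng, max_p=6, max_depth=3, n=50):
    """A small labeled dataset and tree/forest fitting controls."""
    p = int(rng.integers(2, max_p + 1))
    X = rng.normal(size=(n, p))
    j, k = rng.choice(p, size=2, replace=False)
    y = (X[:, j] * X[:, k] + 0.4 * rng.normal(size=n) > 0).astype(int)
    if len(np.unique(y)) < 2:  # pragma: no cover - guard against degenerate draws
        y[0] = 1 - y[0]
    return LabeledDataset(X, y), max_depth
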