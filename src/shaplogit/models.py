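"""The three model families under comparison, behind one predictor contract.

L2-penalized logistic regression, a CART decision tree, and a random forest
are fitted through scikit-learn; what this module owns is the uniform
:class:`Predictor` wrapper (probabilities in [0, 1], labels = probabilities
thresholded at 0.5, capability flags used by the explainers) and reference
implementations of the split criteria — entropy, Gini impurity and
information gain — which serve as ground truth for the delegated learners.

Entropy is reported in bits (log base 2). Gain *rankings* are invariant to
the base, so the delegate's internal convention (natural log) selects the
same splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .data import LabeledDataset
from .exceptions import DegenerateOutcomeError, InvalidArgumentError

__all__ = [
    "Predictor",
    "LogisticFit",
    "SplitRule",
    "entropy",
    "gini_impurity",
    "information_gain",
    "fit_logistic",
    "fit_decision_tree",
    "fit_random_forest",
    "make_model",
]


# ---------------------------------------------------------------------------
# Split criteria.

def _check_proportions(proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("class proportions must be a 1-D vector")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise InvalidArgumentError("class proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError(
            f"class proportions must sum to 1, got {p.sum()!r}"
        )
    return np.clip(p, 0.0, 1.0)


def entropy(proportions) -> float:
    """Shannon entropy H(Y) = -sum p_i log2 p_i in bits; 0*log(0) == 0."""
    p = _check_proportions(proportions)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def gini_impurity(proportions) -> float:
    """Gini impurity G(Y) = 1 - sum p_i^2, the misclassification probability
    of a random element labeled by a random draw from the node."""
    p = _check_proportions(proportions)
    return float(1.0 - (p**2).sum())


@dataclass(frozen=True)
class SplitRule:
    """A binary split: samples with ``side`` True fall on the left.

    ``feature_index``/``threshold`` record where the rule came from; the
    boolean ``side`` vector is what the gain computation consumes.
    """

    feature_index: int
    threshold: float
    side: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray, feature_index: int, threshold: float) -> "SplitRule":
        side = np.asarray(X)[:, feature_index] <= threshold
        return cls(feature_index, float(threshold), side)


def _label_proportions(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels, minlength=2)
    return counts / counts.sum()


def information_gain(labels, split: SplitRule) -> float:
    """Information gain G(Y, S) = H(Y) - sum_i (n_i / N) H(Y_i) in bits.

    Both children of the split must be non-empty.
    """
    y = np.asarray(labels, dtype=np.int64)
    side = np.asarray(split.side, dtype=bool)
    if side.shape != y.shape:
        raise InvalidArgumentError("split side indicator must align with labels")
    n_left = int(side.sum())
    if n_left == 0 or n_left == y.size:
        raise InvalidArgumentError("split must produce two non-empty children")
    h = entropy(_label_proportions(y))
    h_cond = 0.0
    for mask in (side, ~side):
        child = y[mask]
        h_cond += child.size / y.size * entropy(_label_proportions(child))
    return h - h_cond


# ---------------------------------------------------------------------------
# Predictor contract.

@dataclass
class Predictor:
    """Uniform wrapper over a fitted probabilistic classifier.

    ``predict_probability`` returns P(Y=1 | x) in [0, 1];
    ``predict_label`` thresholds it at 0.5. ``is_tree_ensemble`` marks
    models eligible for the fast tree-path interaction explainer.
    """

    estimator: object
    supports_probability: bool = True
    is_tree_ensemble: bool = False

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_probability(X) > 0.5).astype(np.int64)


@dataclass(frozen=True)
class LogisticFit:
    """Coefficients of an L2 logistic regression on the original scale.

    Predictions are reproducible in closed form from these fields:
    P(Y=1 | x) = sigma(intercept + coefficients . x).
    """

    intercept: float
    coefficients: np.ndarray
    names: tuple[str, ...]
    penalty_strength: float

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(X, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("outcome contains a single class")


def fit_logistic(
    data: LabeledDataset,
    penalty_strength: float = 1.0,
    standardize: bool = False,
    max_iter: int = 1000,
) -> tuple[Predictor, LogisticFit]:
    """Fit an L2 logistic regression: logit P(Y=1|x) = b0 + b . x.

    ``penalty_strength`` is the L2 penalty weight (scikit-learn's ``C`` is
    its reciprocal). With ``standardize=True`` columns are z-scored before
    fitting; the returned :class:`LogisticFit` is always mapped back to the
    original scale so that its closed-form link reproduces the predictor.
    """
    _check_two_classes(data.y)
    if penalty_strength < 0:
        raise InvalidArgumentError("penalty_strength must be >= 0")
    X = data.X
    mu = np.zeros(data.p)
    sd = np.ones(data.p)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    C = np.inf if penalty_strength == 0 else 1.0 / penalty_strength
    est = LogisticRegression(C=C, max_iter=max_iter)  # l2 penalty is the default
    est.fit(X, data.y)
    coef_std = est.coef_.ravel()
    coef = coef_std / sd
    intercept = float(est.intercept_[0] - (coef_std * mu / sd).sum())
    fit = LogisticFit(intercept, coef, data.names, penalty_strength)

    class _LogisticEstimator:
        # exposes the closed-form link through the sklearn-like surface
        classes_ = np.array([0, 1])

        def predict_proba(self, Xq):
            p1 = fit.predict_probability(Xq)
            return np.column_stack([1 - p1, p1])

    return Predictor(_LogisticEstimator()), fit


def fit_decision_tree(
    data: LabeledDataset,
    criterion: str = "gini",
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    seed: int = 0,
) -> Predictor:
    """Fit a CART decision tree (axis-aligned binary splits).

    Defaults are the delegate's "naive" settings: unbounded depth, Gini
    criterion. The resulting decision function is a staircase in x.
    """
    _check_two_classes(data.y)
    if criterion not in ("gini", "entropy"):
        raise InvalidArgumentError("criterion must be 'gini' or 'entropy'")
    est = DecisionTreeClassifier(
        criterion=criterion,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    )
    est.fit(data.X, data.y)
    return Predictor(est, is_tree_ensemble=True)


def fit_random_forest(
    data: LabeledDataset,
    n_trees: int = 100,
    max_features: int | str | None = "sqrt",
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    bootstrap: bool = True,
    criterion: str = "gini",
    class_weight: str | None = None,
    seed: int = 0,
) -> Predictor:
    """Fit a random forest of de-correlated CART trees.

    The ensemble probability is the mean of the per-tree leaf
    probabilities. ``class_weight="balanced"`` enables optional
    inverse-frequency weighting for imbalanced outcomes (off by default).
    """
    _check_two_classes(data.y)
    if n_trees < 1:
        raise InvalidArgumentError("n_trees must be >= 1")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        bootstrap=bootstrap,
        criterion=criterion,
        class_weight=class_weight,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(data.X, data.y)
    return Predictor(est, is_tree_ensemble=True)


def make_model(spec: dict):
    """Build a fitting function from a JSON-style config block.

    ``spec`` is ``{"model": "lr" | "dt" | "rf", ...hyperparameters}``;
    returns ``fit(data) -> Predictor``.
    """
    spec = dict(spec)
    kind = spec.pop("model")
    if kind == "lr":
        return lambda data: fit_logistic(data, **spec)[0]
    if kind == "dt":
        return lambda data: fit_decision_tree(data, **spec)
    if kind == "rf":
        return lambda data: fit_random_forest(data, **spec)
    raise InvalidArgumentError(f"unknown model kind {kind!r}")
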