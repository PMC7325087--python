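"""Exact model-agnostic Shapley attributions by coalition enumeration.

The value of a coalition S for a sample x is the interventional
expectation over a background set B:

    v(S) = mean_{b in B} f(x_S, b_{M \\ S})

i.e. the model is evaluated on hybrid rows that take x's values on S and a
background row's values elsewhere. From the full table of 2^p coalition
values we assemble

* per-feature Shapley values
      phi_j = sum_{S subseteq M\\{j}} |S|! (p-|S|-1)! / p! [v(S u {j}) - v(S)]

* pairwise Shapley interaction values (the Shapley interaction index with
  the total interaction split evenly across the two ordered pairs)
      Phi_jk = sum_{S subseteq M\\{j,k}} |S|! (p-|S|-2)! / (2 (p-1)!)
               * [v(S u {j,k}) - v(S u {j}) - v(S u {k}) + v(S)]

with the diagonal defined as the remainder Phi_jj = phi_j - sum_{k != j}
Phi_jk, so that every row of the per-sample p x p matrix sums back to
phi_j (the interaction tensor *completes* the additive explanation).

Cost is 2^p model evaluations per sample, so the enumeration is capped at
p <= 12 for values and p <= 10 for interactions; tree ensembles beyond
that must go through :func:`shaplogit.treeshap.tree_interactions`, for
which this module is the correctness oracle.

By default the model's probability output is explained; ``scale="margin"``
explains the log-odds instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .exceptions import FeatureLimitError, InvalidArgumentError, SchemaError
from .models import Predictor

__all__ = [
    "BackgroundSet",
    "ShapleyExplanation",
    "InteractionTensor",
    "coalition_value",
    "exact_shapley",
    "exact_interactions",
    "MAX_EXACT_P",
    "MAX_EXACT_INTERACTION_P",
]

MAX_EXACT_P = 12
MAX_EXACT_INTERACTION_P = 10


@dataclass(frozen=True)
class BackgroundSet:
    """Reference rows defining the marginal expectation E[f]."""

    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] < 1:
            raise InvalidArgumentError("background must contain at least one row")
        object.__setattr__(self, "X", X)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def subsample(cls, X: np.ndarray, max_rows: int = 100, seed: int = 0) -> "BackgroundSet":
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= max_rows:
            return cls(X)
        idx = np.random.default_rng(seed).choice(X.shape[0], size=max_rows, replace=False)
        return cls(X[idx])


@dataclass(frozen=True)
class ShapleyExplanation:
    """Per-sample additive attributions: f(x_i) = base_value + sum_j phi[i, j]."""

    base_value: float
    phi: np.ndarray
    names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.names) if self.names else None
        return pd.DataFrame(self.phi, columns=cols)


@dataclass(frozen=True)
class InteractionTensor:
    """Per-sample symmetric p x p attribution matrices.

    ``values[i]`` has main effects on the diagonal and halved pairwise
    interaction attributions off the diagonal; each row sums to the
    corresponding Shapley value phi[i, j].
    """

    values: np.ndarray
    base_value: float = 0.0
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise InvalidArgumentError("interaction tensor must be n x p x p")
        object.__setattr__(self, "values", v)

    @property
    def phi(self) -> np.ndarray:
        """Row sums recover the per-feature Shapley values."""
        return self.values.sum(axis=2)

    def to_long_frame(self) -> pd.DataFrame:
        n, p, _ = self.values.shape
        names = list(self.names) if self.names else [f"X{j + 1}" for j in range(p)]
        i, a, b = np.meshgrid(np.arange(n), np.arange(p), np.arange(p), indexing="ij")
        return pd.DataFrame(
            {
                "sample": i.ravel(),
                "feature_a": np.asarray(names)[a.ravel()],
                "feature_b": np.asarray(names)[b.ravel()],
                "value": self.values.ravel(),
            }
        )


def _predict(model: Predictor, X: np.ndarray, scale: str) -> np.ndarray:
    prob = model.predict_probability(X)
    if scale == "probability":
        return prob
    if scale == "margin":
        prob = np.clip(prob, 1e-12, 1 - 1e-12)
        return np.log(prob / (1 - prob))
    raise InvalidArgumentError("scale must be 'probability' or 'margin'")


def coalition_value(
    model: Predictor,
    x: np.ndarray,
    coalition,
    background: BackgroundSet,
    scale: str = "probability",
) -> float:
    """v(S): mean model output over background rows with x imposed on S."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != background.p:
        raise SchemaError(
            f"sample has {x.size} features, background has {background.p}"
        )
    S = np.asarray(sorted(set(int(j) for j in coalition)), dtype=int)
    if S.size and (S.min() < 0 or S.max() >= x.size):
        raise InvalidArgumentError("coalition indices out of range")
    Z = background.X.copy()
    if S.size:
        Z[:, S] = x[S]
    return float(_predict(model, Z, scale).mean())


def _coalition_table(
    model: Predictor, x: np.ndarray, background: BackgroundSet, scale: str
) -> np.ndarray:
    """All 2^p coalition values for one sample, indexed by bitmask."""
    p = x.size
    m = background.m
    n_masks = 1 << p
    # hybrid rows for every (mask, background row) pair, one batched predict
    Z = np.tile(background.X, (n_masks, 1))
    for j in range(p):
        mask_has_j = (np.arange(n_masks) >> j) & 1 == 1
        rows = np.repeat(mask_has_j, m)
        Z[rows, j] = x[j]
    out = _predict(model, Z, scale)
    return out.reshape(n_masks, m).mean(axis=1)


def _shapley_from_table(v: np.ndarray, p: int) -> np.ndarray:
    """Combine a coalition-value table into phi via the Shapley weights."""
    w = np.array(
        [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    )
    masks = np.arange(1 << p)
    sizes = np.array([bin(mk).count("1") for mk in masks])
    phi = np.zeros(p)
    for j in range(p):
        without_j = masks[(masks >> j) & 1 == 0]
        s = sizes[without_j]
        phi[j] = (w[s] * (v[without_j | (1 << j)] - v[without_j])).sum()
    return phi


def _interactions_from_table(v: np.ndarray, p: int) -> np.ndarray:
    """Off-diagonal Shapley interaction values (halved per ordered pair)."""
    if p < 2:
        return np.zeros((p, p))
    w2 = np.array(
        [
            factorial(s) * factorial(p - s - 2) / (2.0 * factorial(p - 1))
            for s in range(p - 1)
        ]
    )
    masks = np.arange(1 << p)
    sizes = np.array([bin(mk).count("1") for mk in masks])
    out = np.zeros((p, p))
    for j in range(p):
        for k in range(j + 1, p):
            both = (1 << j) | (1 << k)
            S = masks[(masks & both) == 0]
            s = sizes[S]
            delta = v[S | both] - v[S | (1 << j)] - v[S | (1 << k)] + v[S]
            val = (w2[s] * delta).sum()
            out[j, k] = out[k, j] = val
    return out


def _check_p(p: int, cap: int, what: str) -> None:
    if p > cap:
        raise FeatureLimitError(
            f"{what} enumerates 2^p coalitions and is capped at p <= {cap} "
            f"(got p = {p}); use the tree-path explainer for tree ensembles"
        )


def exact_shapley(
    model: Predictor,
    X: np.ndarray,
    background: BackgroundSet,
    scale: str = "probability",
) -> ShapleyExplanation:
    """Exact Shapley values for every row of X by full coalition enumeration."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != background.p:
        raise SchemaError("X and background column counts differ")
    _check_p(X.shape[1], MAX_EXACT_P, "exact_shapley")
    n, p = X.shape
    phi = np.empty((n, p))
    for i in range(n):
        v = _coalition_table(model, X[i], background, scale)
        phi[i] = _shapley_from_table(v, p)
    base = float(_predict(model, background.X, scale).mean())
    return ShapleyExplanation(base, phi)


def exact_interactions(
    model: Predictor,
    X: np.ndarray,
    background: BackgroundSet,
    scale: str = "probability",
) -> InteractionTensor:
    """Exact pairwise Shapley interaction tensor by full enumeration.

    Row-sum consistency with :func:`exact_shapley` is enforced by
    construction: the diagonal absorbs phi_j minus the off-diagonal row sum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != background.p:
        raise SchemaError("X and background column counts differ")
    _check_p(X.shape[1], MAX_EXACT_INTERACTION_P, "exact_interactions")
    n, p = X.shape
    values = np.empty((n, p, p))
    for i in range(n):
        v = _coalition_table(model, X[i], background, scale)
        phi = _shapley_from_table(v, p)
        off = _interactions_from_table(v, p)
        np.fill_diagonal(off, phi - off.sum(axis=1))
        values[i] = off
    base = float(_predict(model, background.X, scale).mean())
    return InteractionTensor(values, base)
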