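"""Fast interventional Shapley interaction values for tree ensembles.

Computes the same quantities as :func:`shaplogit.shapley.exact_interactions`
— interventional (background-marginalized) Shapley values and pairwise
interaction values — but in time polynomial in the tree size instead of
2^p model evaluations, by exploiting the structure of CART ensembles.

For one explained sample x, one background row b and one leaf L with value
c_L, the hybrid input z = (x_S, b_{M \\ S}) reaches L iff every condition
on L's root path holds. Grouping path conditions by feature, each distinct
path feature falls into one of four states:

* both x and b satisfy all its conditions  -> always on the path (dummy),
* only x satisfies                          -> must be *in* the coalition (set R),
* only b satisfies                          -> must be *out* (set Q),
* neither satisfies                         -> the leaf is unreachable.

The coalition game restricted to that leaf is therefore the simple
"unanimity-with-veto" game  g(S) = c_L * 1{R subseteq S} * 1{Q cap S = 0},
whose Shapley values and pairwise interaction values have closed forms
that depend only on r = |R|, q = |Q| and each feature's membership:

    phi_j     =  c_L * A(r-1, r+q)   for j in R
    phi_j     = -c_L * A(r,   r+q)   for j in Q
    Phi_jk    =  c_L * B(r-2, r+q)   for j,k in R
    Phi_jk    = -c_L * B(r-1, r+q)   for j in R, k in Q (either order)
    Phi_jk    =  c_L * B(r,   r+q)   for j,k in Q

where, with f = p - (r+q) free features available to pad the coalition,

    A(m, r+q) = sum_t C(f, t) (m+t)! (p-1-m-t)! / p!
    B(m, r+q) = sum_t C(f, t) (m+t)! (p-2-m-t)! / (2 (p-1)!)

(both tabulated exactly with rational arithmetic). Features in neither R
nor Q receive nothing from the leaf. Summing over leaves, trees and
background rows, and dividing the ensemble contribution by the number of
trees (the forest probability is the mean of tree probabilities), yields
the full tensor. Local accuracy holds by construction: for each (x, b)
pair the per-leaf games telescope to f(x) - f(b).

Only the probability scale is supported: the ensemble log-odds is not an
average of per-tree outputs, so a margin-scale tensor cannot be assembled
tree by tree.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np

from .exceptions import CapabilityError, InvalidArgumentError, SchemaError
from .models import Predictor
from .shapley import BackgroundSet, InteractionTensor

__all__ = ["tree_interactions"]


def _weight_tables(p: int, max_rq: int) -> tuple[np.ndarray, np.ndarray]:
    """A[m, rq] and B[m, rq] for m in 0..max_rq, rq in 0..max_rq."""
    A = np.zeros((max_rq + 1, max_rq + 1))
    B = np.zeros((max_rq + 1, max_rq + 1))
    fp = Fraction(factorial(p))
    fp1 = Fraction(2 * factorial(p - 1)) if p >= 2 else None
    for rq in range(min(max_rq, p) + 1):
        f = p - rq
        for m in range(rq + 1):
            a = Fraction(0)
            b = Fraction(0)
            for t in range(f + 1):
                c = comb(f, t)
                if m + t <= p - 1:
                    a += c * Fraction(factorial(m + t) * factorial(p - 1 - m - t))
                if p >= 2 and m + t <= p - 2:
                    b += c * Fraction(factorial(m + t) * factorial(p - 2 - m - t))
            A[m, rq] = float(a / fp)
            if p >= 2:
                B[m, rq] = float(b / fp1)
    return A, B


def _leaf_paths(tree) -> list[tuple[int, list[tuple[int, float, bool]]]]:
    """DFS: (leaf node id, [(feature, threshold, goes_left), ...]) per leaf."""
    out: list[tuple[int, list[tuple[int, float, bool]]]] = []
    stack: list[tuple[int, list[tuple[int, float, bool]]]] = [(0, [])]
    left, right = tree.children_left, tree.children_right
    while stack:
        node, conds = stack.pop()
        if left[node] == -1:
            out.append((node, conds))
            continue
        f, thr = int(tree.feature[node]), float(tree.threshold[node])
        stack.append((left[node], conds + [(f, thr, True)]))
        stack.append((right[node], conds + [(f, thr, False)]))
    return out


def _leaf_prob(tree, node: int, classes: np.ndarray) -> float:
    """Fraction of class 1 at a leaf (robust to count vs fraction storage)."""
    v = np.asarray(tree.value[node], dtype=float).ravel()
    total = v.sum()
    if total <= 0:
        return 0.0
    where = np.flatnonzero(classes == 1)
    return float(v[where[0]] / total) if where.size else 0.0


def _component_trees(model: Predictor):
    est = model.estimator
    if hasattr(est, "estimators_"):
        weight = 1.0 / len(est.estimators_)
        return [(t, weight) for t in est.estimators_]
    if hasattr(est, "tree_"):
        return [(est, 1.0)]
    raise CapabilityError(
        "tree_interactions requires a fitted decision tree or tree ensemble"
    )


def tree_interactions(
    model: Predictor,
    X: np.ndarray,
    background: BackgroundSet,
    scale: str = "probability",
) -> InteractionTensor:
    """Interventional Shapley interaction tensor for a CART tree or forest.

    Agrees elementwise with :func:`shaplogit.shapley.exact_interactions`
    under the same background set; see the module docstring for the
    algorithm. Raises :class:`CapabilityError` for non-tree models and for
    the (non-additive) margin scale.
    """
    if not model.is_tree_ensemble:
        raise CapabilityError("model is not a tree ensemble")
    if scale != "probability":
        raise CapabilityError(
            "tree_interactions explains the probability scale only"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Bg = background.X
    if X.shape[1] != background.p:
        raise SchemaError("X and background column counts differ")
    n, p = X.shape
    m = Bg.shape[0]
    if p < 1:
        raise InvalidArgumentError("need at least one feature")

    trees = _component_trees(model)
    max_rq = 0
    parsed = []
    for est, weight in trees:
        tree = est.tree_
        classes = np.asarray(est.classes_)
        leaves = []
        for node, conds in _leaf_paths(tree):
            per_feat: dict[int, list[tuple[float, bool]]] = {}
            for f, thr, goes_left in conds:
                per_feat.setdefault(f, []).append((thr, goes_left))
            feats = sorted(per_feat)
            max_rq = max(max_rq, len(feats))
            leaves.append((feats, per_feat, _leaf_prob(tree, node, classes) * weight))
        parsed.append(leaves)

    Atab, Btab = _weight_tables(p, max_rq)

    phi = np.zeros((n, p))
    off = np.zeros((n, p, p))
    for leaves in parsed:
        for feats, per_feat, c in leaves:
            if c == 0.0 or not feats:
                # constant-root tree or zero-probability leaf: no attribution
                continue
            d = len(feats)
            xok = np.empty((d, n), dtype=bool)
            bok = np.empty((d, m), dtype=bool)
            for idx, f in enumerate(feats):
                sx = np.ones(n, dtype=bool)
                sb = np.ones(m, dtype=bool)
                for thr, goes_left in per_feat[f]:
                    if goes_left:
                        sx &= X[:, f] <= thr
                        sb &= Bg[:, f] <= thr
                    else:
                        sx &= X[:, f] > thr
                        sb &= Bg[:, f] > thr
                xok[idx] = sx
                bok[idx] = sb

            R = xok[:, :, None] & ~bok[:, None, :]        # (d, n, m)
            Q = ~xok[:, :, None] & bok[:, None, :]
            alive = (xok[:, :, None] | bok[:, None, :]).all(axis=0)
            if not alive.any():
                continue
            r = R.sum(axis=0, dtype=np.int16)
            rq = r + Q.sum(axis=0, dtype=np.int16)

            a_r = Atab[np.clip(r - 1, 0, None), rq]
            a_q = Atab[r, rq]
            b_rr = Btab[np.clip(r - 2, 0, None), rq]
            b_rq = Btab[np.clip(r - 1, 0, None), rq]
            b_qq = Btab[r, rq]
            for idx in range(d):
                contrib = np.where(R[idx] & alive, a_r, 0.0)
                contrib -= np.where(Q[idx] & alive, a_q, 0.0)
                phi[:, feats[idx]] += c * contrib.sum(axis=1)
            for idx in range(d):
                for jdx in range(idx + 1, d):
                    val = np.where(R[idx] & R[jdx] & alive, b_rr, 0.0)
                    val -= np.where(
                        ((R[idx] & Q[jdx]) | (Q[idx] & R[jdx])) & alive, b_rq, 0.0
                    )
                    val += np.where(Q[idx] & Q[jdx] & alive, b_qq, 0.0)
                    s = c * val.sum(axis=1)
                    off[:, feats[idx], feats[jdx]] += s
                    off[:, feats[jdx], feats[idx]] += s

    phi /= m
    off /= m
    for j in range(p):
        off[:, j, j] = phi[:, j] - (off[:, j].sum(axis=1) - off[:, j, j])
    base = float(model.predict_probability(Bg).mean())
    return InteractionTensor(off, base)
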