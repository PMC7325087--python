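"""The hybrid procedure: screen tree-ensemble interaction attributions,
append the top pairs as product predictors, refit logistic regression.

Pipeline (:func:`fit_hybrid`):

1. fit a random forest to the training data;
2. compute the per-sample Shapley interaction tensor on (a subsample of)
   the training rows — the tree-path explainer for ensembles, the
   brute-force enumerator otherwise;
3. aggregate to a global ranking by summing absolute per-sample
   interaction attributions over samples (raw sums would let opposing
   signs cancel and hide genuinely salient interactions);
4. select pairs (fixed ``k`` or the elbow in the score curve);
5. append one product column per selected pair to *both* the training and
   test design matrices — the test set is touched only through the
   train-selected pair list, so no information leaks;
6. refit an L2 logistic regression on the augmented training matrix and
   score it on the augmented test matrix. Wald p-values for every term
   come from an unpenalized maximum-likelihood refit, so a spurious
   appended interaction shows up as non-significant ("protecting the
   null hypothesis").

Candidate pairs are distinct predictors only — quadratic self-terms are
not considered. All randomness flows from a single seed expanded into
per-stage seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import LabeledDataset
from .exceptions import IntegrityError, InvalidArgumentError, SchemaError
from .models import LogisticFit, Predictor, fit_logistic, fit_random_forest
from .shapley import (
    MAX_EXACT_INTERACTION_P,
    BackgroundSet,
    InteractionTensor,
    exact_interactions,
)
from .treeshap import tree_interactions
from .evaluate import auroc

__all__ = [
    "InteractionRanking",
    "AugmentedDesign",
    "HybridConfig",
    "HybridResult",
    "rank_interactions",
    "select_pairs",
    "augment_design",
    "compute_interaction_tensor",
    "fit_hybrid",
]


@dataclass(frozen=True)
class InteractionRanking:
    """Global pairwise importances: (a, b, score) with a < b, scores
    non-increasing, ties broken lexicographically by (a, b)."""

    entries: tuple[tuple[int, int, float], ...]
    names: tuple[str, ...] = ()

    def pairs(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, _ in self.entries]

    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.entries])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, s in self.entries:
            rows.append(
                {
                    "feature_a": self.names[a] if self.names else a,
                    "feature_b": self.names[b] if self.names else b,
                    "score": s,
                }
            )
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "score"])


def rank_interactions(
    tensor: InteractionTensor, names: tuple[str, ...] = ()
) -> InteractionRanking:
    """Aggregate a per-sample interaction tensor into a global ranking.

    score(a, b) = sum_i |Phi[i, a, b]| + |Phi[i, b, a]|  for a < b.
    """
    V = tensor.values
    if not np.all(np.isfinite(V)):
        raise IntegrityError("interaction tensor contains non-finite values")
    asym = np.abs(V - V.transpose(0, 2, 1)).max() if V.size else 0.0
    if asym > 1e-6:
        raise IntegrityError(f"interaction tensor asymmetric (max |diff| {asym:.3g})")
    p = V.shape[1]
    entries = []
    for a in range(p):
        for b in range(a + 1, p):
            score = float(np.abs(V[:, a, b]).sum() + np.abs(V[:, b, a]).sum())
            entries.append((a, b, score))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return InteractionRanking(tuple(entries), tuple(names))


def select_pairs(
    ranking: InteractionRanking,
    k: int | None = None,
    strategy: str = "top_k",
) -> list[tuple[int, int]]:
    """Choose pairs to append: the first ``k`` under ``top_k``, or the
    prefix before the largest consecutive score drop (ratio gap) under
    ``elbow`` (at least one pair whenever any score is positive)."""
    pairs = ranking.pairs()
    scores = ranking.scores()
    if strategy == "top_k":
        if k is None or k < 0:
            raise InvalidArgumentError("top_k selection needs k >= 0")
        if k > len(pairs):
            warnings.warn(
                f"k={k} exceeds the {len(pairs)} available pairs; clamping",
                stacklevel=2,
            )
            k = len(pairs)
        return pairs[:k]
    if strategy == "elbow":
        if len(scores) == 0 or scores[0] <= 0:
            return []
        best_cut, best_ratio = 1, -np.inf
        for i in range(len(scores) - 1):
            if scores[i] <= 0:
                break
            ratio = np.inf if scores[i + 1] <= 0 else scores[i] / scores[i + 1]
            if ratio > best_ratio:
                best_ratio, best_cut = ratio, i + 1
        return pairs[:best_cut]
    raise InvalidArgumentError("strategy must be 'top_k' or 'elbow'")


@dataclass(frozen=True)
class AugmentedDesign:
    """A dataset with product columns appended for the given pairs."""

    data: LabeledDataset
    pairs: tuple[tuple[int, int], ...]
    appended_names: tuple[str, ...]


def augment_design(data: LabeledDataset, pairs) -> AugmentedDesign:
    """Append one elementwise product column per (a, b) pair.

    Appended columns are named ``"<A>_x_<B>"`` from the parent names and
    preserve the order of ``pairs``; original columns are untouched.
    """
    pairs = tuple((int(a), int(b)) for a, b in pairs)
    for a, b in pairs:
        if not (0 <= a < data.p and 0 <= b < data.p):
            raise InvalidArgumentError(f"pair ({a}, {b}) out of range for p={data.p}")
    new_names = tuple(f"{data.names[a]}_x_{data.names[b]}" for a, b in pairs)
    all_names = data.names + new_names
    if len(set(all_names)) != len(all_names):
        raise SchemaError("appended product names collide with existing columns")
    if not pairs:
        return AugmentedDesign(data, (), ())
    prods = np.column_stack([data.X[:, a] * data.X[:, b] for a, b in pairs])
    X = np.hstack([data.X, prods])
    return AugmentedDesign(LabeledDataset(X, data.y, all_names), pairs, new_names)


@dataclass(frozen=True)
class HybridConfig:
    """Tunable knobs of the hybrid pipeline.

    The internal forest is depth-limited (depth 5, >= 10 samples per
    leaf): pairwise interactions surface in shallow trees, and leaf count
    drives the explainer's cost. ``explain_rows``/``background_rows``
    bound the training subsample the tensor is computed on.
    """

    n_trees: int = 100
    max_depth: int | None = 5
    min_samples_leaf: int = 10
    max_features: int | str | None = "sqrt"
    penalty_strength: float = 1.0
    standardize: bool = True
    explain_rows: int = 256
    background_rows: int = 64
    scale: str = "probability"


@dataclass(frozen=True)
class HybridResult:
    """Outcome of the hybrid pipeline on one train/test split."""

    selected_pairs: tuple[tuple[int, int], ...]
    selected_names: tuple[str, ...]
    ranking: InteractionRanking
    fit: LogisticFit
    coefficients: pd.DataFrame  # term, coefficient, odds_ratio, p_value
    test_auroc: float
    test_accuracy: float
    forest: Predictor
    augmented_names: tuple[str, ...] = field(default=())

    def pair_pvalues(self) -> dict[str, float]:
        sel = self.coefficients[self.coefficients.term.isin(self.selected_names)]
        return dict(zip(sel.term, sel.p_value))


def compute_interaction_tensor(
    model: Predictor,
    X: np.ndarray,
    background: BackgroundSet,
    scale: str = "probability",
) -> InteractionTensor:
    """Dispatch: tree-path explainer for ensembles (any p), brute force
    otherwise (p capped)."""
    if model.is_tree_ensemble and scale == "probability":
        return tree_interactions(model, X, background, scale=scale)
    if X.shape[1] > MAX_EXACT_INTERACTION_P:
        raise InvalidArgumentError(
            f"p={X.shape[1]} exceeds the brute-force cap "
            f"({MAX_EXACT_INTERACTION_P}) and the model has no tree fast path"
        )
    return exact_interactions(model, X, background, scale=scale)


def _wald_pvalues(design: LabeledDataset) -> pd.DataFrame:
    """Unpenalized ML refit (z-scored columns) for Wald inference per term."""
    X = design.X
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    exog = sm.add_constant(Z, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(design.y, exog).fit(disp=0, maxiter=200)
            pvals = np.asarray(res.pvalues)[1:]
        except Exception:  # perfect separation or non-convergence
            pvals = np.full(design.p, np.nan)
    return pd.DataFrame({"term": list(design.names), "p_value": pvals})


def fit_hybrid(
    train: LabeledDataset,
    test: LabeledDataset,
    config: HybridConfig | None = None,
    k: int | None = None,
    strategy: str = "top_k",
    seed: int = 0,
) -> HybridResult:
    """Run the full hybrid pipeline on a train/test split.

    ``k=None`` under ``top_k`` defaults to ``min(10, p*(p-1)/2)``. With
    ``k=0`` the pipeline reduces exactly to a plain L2 logistic
    regression on the original design.
    """
    if train.names != test.names:
        raise SchemaError("train and test must share the same predictor schema")
    cfg = config or HybridConfig()
    if k is None and strategy == "top_k":
        k = min(10, train.p * (train.p - 1) // 2)

    # one seed, expanded into independent per-stage streams
    children = np.random.SeedSequence(seed).spawn(3)
    rf_seed, row_seed, bg_seed = (int(c.generate_state(1)[0] % (2**31)) for c in children)

    try:
        forest = fit_random_forest(
            train,
            n_trees=cfg.n_trees,
            max_features=cfg.max_features,
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_samples_leaf,
            seed=rf_seed,
        )
    except Exception as exc:
        raise type(exc)(f"hybrid stage 'forest': {exc}") from exc

    rng = np.random.default_rng(row_seed)
    idx = (
        rng.choice(train.n, size=cfg.explain_rows, replace=False)
        if train.n > cfg.explain_rows
        else np.arange(train.n)
    )
    background = BackgroundSet.subsample(train.X, cfg.background_rows, seed=bg_seed)
    try:
        tensor = compute_interaction_tensor(
            forest, train.X[idx], background, scale=cfg.scale
        )
    except Exception as exc:
        raise type(exc)(f"hybrid stage 'interactions': {exc}") from exc

    ranking = rank_interactions(tensor, train.names)
    pairs = select_pairs(ranking, k=k, strategy=strategy)

    aug_train = augment_design(train, pairs)
    aug_test = augment_design(test, pairs)

    try:
        predictor, fit = fit_logistic(
            aug_train.data,
            penalty_strength=cfg.penalty_strength,
            standardize=cfg.standardize,
        )
    except Exception as exc:
        raise type(exc)(f"hybrid stage 'logistic': {exc}") from exc

    scores = predictor.predict_probability(aug_test.data.X)
    test_auc = auroc(aug_test.data.y, scores)
    test_acc = float(((scores > 0.5).astype(int) == aug_test.data.y).mean())

    coef = pd.DataFrame(
        {
            "term": list(aug_train.data.names),
            "coefficient": fit.coefficients,
            "odds_ratio": fit.odds_ratios(),
        }
    ).merge(_wald_pvalues(aug_train.data), on="term", how="left")

    return HybridResult(
        selected_pairs=tuple(pairs),
        selected_names=aug_train.appended_names,
        ranking=ranking,
        fit=fit,
        coefficients=coef,
        test_auroc=test_auc,
        test_accuracy=test_acc,
        forest=forest,
        augmented_names=aug_train.data.names,
    )
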