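"""Model comparison machinery: AUROC, stratified cross-validation,
bootstrap confidence intervals, interaction-strength sweeps, smoothing,
and paired significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import mannwhitneyu, ttest_rel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset
from .exceptions import (
    InvalidArgumentError,
    StratificationError,
    UndefinedMetricError,
)
from .models import make_model
from .simulate import gen_interaction_dgp

__all__ = [
    "CVResult",
    "SweepResult",
    "ComparisonResult",
    "auroc",
    "cross_validate",
    "bootstrap_ci",
    "interaction_sweep",
    "smooth_curve",
    "compare_models",
]


def auroc(labels, scores) -> float:
    """C-statistic: probability a random positive outscores a random
    negative, ties counted 1/2 (Mann-Whitney formulation)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold scores from stratified k-fold cross-validation."""

    auroc_per_fold: np.ndarray
    accuracy_per_fold: np.ndarray
    k: int
    seed: int

    @property
    def mean_auroc(self) -> float:
        return float(self.auroc_per_fold.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy_per_fold.mean())


def cross_validate(model_spec: dict, data: LabeledDataset, k: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold CV; each sample is scored exactly once out-of-fold.

    ``model_spec`` is a config block accepted by
    :func:`shaplogit.models.make_model`, e.g. ``{"model": "rf", "seed": 1}``.
    """
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < k:
        raise StratificationError(
            f"minority class has {counts.min()} members, fewer than k={k} folds"
        )
    fit = make_model(model_spec)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, accs = [], []
    for train_idx, test_idx in skf.split(data.X, data.y):
        sub = LabeledDataset(data.X[train_idx], data.y[train_idx], data.names)
        model = fit(sub)
        scores = model.predict_probability(data.X[test_idx])
        y_test = data.y[test_idx]
        aucs.append(auroc(y_test, scores))
        accs.append(float(((scores > 0.5).astype(int) == y_test).mean()))
    return CVResult(np.array(aucs), np.array(accs), k, seed)


def bootstrap_ci(
    metric,
    labels,
    scores,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(labels, scores)``.

    Label/score pairs are resampled jointly with replacement. A resample
    containing a single class (on which e.g. AUROC is undefined) is
    redrawn; redraws are counted and capped.
    """
    if reps < 1:
        raise InvalidArgumentError("reps must be >= 1")
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    redraws = 0
    for i in range(reps):
        while True:
            idx = rng.integers(0, y.size, size=y.size)
            try:
                vals[i] = metric(y[idx], s[idx])
                break
            except UndefinedMetricError:
                redraws += 1
                if redraws > max_redraws:
                    raise UndefinedMetricError(
                        "too many degenerate bootstrap resamples"
                    ) from None
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )


@dataclass(frozen=True)
class SweepResult:
    """Held-out accuracy per model family across an interaction-strength grid."""

    records: pd.DataFrame  # columns: beta, model, seed, accuracy

    def mean_curve(self, model: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.records[self.records.model == model]
        grouped = sub.groupby("beta")["accuracy"].mean().sort_index()
        return grouped.index.to_numpy(), grouped.to_numpy()


DEFAULT_SWEEP_SPECS = {
    "lr": {"model": "lr"},
    "dt": {"model": "dt"},
    "rf": {"model": "rf"},
}


def interaction_sweep(
    betas,
    n_train: int = 5000,
    n_test: int = 5000,
    model_specs: dict | None = None,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> SweepResult:
    """For each interaction strength beta: simulate train/test data from the
    four-predictor interaction process, fit each model family, record
    held-out accuracy; repeated over ``n_seeds`` replicate seeds."""
    betas = list(betas)
    if not betas:
        raise InvalidArgumentError("beta grid must be non-empty")
    specs = model_specs or DEFAULT_SWEEP_SPECS
    rows = []
    for beta in betas:
        for rep in range(n_seeds):
            seed = base_seed + 10_000 * rep
            train = gen_interaction_dgp(n_train, beta, seed)
            test = gen_interaction_dgp(n_test, beta, seed + 1)
            for name, spec in specs.items():
                spec = dict(spec)
                if spec.get("model") in ("dt", "rf"):
                    spec.setdefault("seed", seed)
                model = make_model(spec)(train)
                acc = float((model.predict_label(test.X) == test.y).mean())
                rows.append(
                    {"beta": beta, "model": name, "seed": seed, "accuracy": acc}
                )
    return SweepResult(pd.DataFrame(rows))


def smooth_curve(y, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Reproduces exactly any input that is globally polynomial of degree
    <= ``polyorder``.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0 or window <= polyorder or window > y.size:
        raise InvalidArgumentError(
            "window must be odd, greater than polyorder, and at most len(y)"
        )
    return savgol_filter(y, window_length=window, polyorder=polyorder)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two score vectors."""

    mean_difference: float
    t_statistic: float
    t_pvalue: float
    u_statistic: float
    u_pvalue: float
    degenerate: bool  # zero variance in the paired differences


def compare_models(scores_a, scores_b) -> ComparisonResult:
    """Paired t-test, Mann-Whitney U and mean difference (a minus b).

    Two-sided p-values; no multiplicity correction (single planned
    comparison). Zero-variance differences set the ``degenerate`` flag and
    leave the t-statistic as NaN.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidArgumentError("need paired vectors of equal length >= 2")
    diff = a - b
    degenerate = bool(np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0.0))
    if degenerate:
        t_stat, t_p = float("nan"), float("nan")
    else:
        t = ttest_rel(a, b)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    u = mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        mean_difference=float(diff.mean()),
        t_statistic=t_stat,
        t_pvalue=t_p,
        u_statistic=float(u.statistic),
        u_pvalue=float(u.pvalue),
        degenerate=degenerate,
    )
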