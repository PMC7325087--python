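"""Synthetic data generators for the model-comparison study.

Four data-generating processes (DGPs) are provided:

``linear``
    One standard-normal predictor, outcome ``Y = 1{3*X1 + eps > 0}`` with
    standard logistic noise — the log-odds of the outcome are exactly
    linear in the predictor, so a logistic regression is the true model.

``nonlinear_interval``
    ``X1 ~ U(-10, 10)`` and ``Y = 1{X1 + 0.25*eps in (-6,-2.5) u (0,1.5)}``
    with standard normal ``eps`` — a discontinuous interval-membership rule
    that no monotone link can capture, favouring recursive partitioning.

``interaction4``
    Four predictors, linear log-odds plus a product interaction between the
    last two: ``Y = 1{sigma(X1+X2+X3+X4 + beta*X3*X4) > 0.5}``. Because
    ``sigma(z) > 0.5  iff  z > 0``, labels are a deterministic function of
    the drawn predictors: ``Y = 1{sum X_i + beta*X3*X4 > 0}``.

``epistasis``
    A two-locus pure-epistasis trait: biallelic genotypes coded {0, 1, 2}
    under Hardy–Weinberg equilibrium, trait = XOR of the two carrier
    indicators (exactly one locus carries a minor allele), labels flipped
    with a small probability, plus independent non-causal loci. The default
    minor-allele frequency ``1 - 1/sqrt(2)`` makes the carrier probability
    exactly 1/2, so each causal locus is *marginally* independent of the
    trait — main-effects-only models score at chance while the pairwise
    product term separates the classes.

All generators are pure functions of their arguments: a fixed seed yields
a bit-identical dataset. Logistic noise is drawn by inverse-CDF transform
of a uniform variate for cross-platform reproducibility.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict

import numpy as np

from .data import LabeledDataset
from .exceptions import InvalidArgumentError

__all__ = [
    "DGP",
    "DGPConfig",
    "gen_linear_dgp",
    "gen_nonlinear_dgp",
    "gen_interaction_dgp",
    "gen_epistasis_dgp",
    "generate",
    "linear_labels",
    "interval_labels",
    "interaction_labels",
    "xor_labels",
    "EPISTASIS_MAF",
]

# Minor-allele frequency at which P(carrier) = 1 - (1-q)^2 = 1/2, giving a
# pure-epistasis trait with zero marginal locus effects.
EPISTASIS_MAF = 1.0 - 2.0 ** -0.5


class DGP(str, enum.Enum):
    linear = "linear"
    nonlinear_interval = "nonlinear_interval"
    interaction4 = "interaction4"
    epistasis = "epistasis"


@dataclass(frozen=True)
class DGPConfig:
    """Which generator to run and with what parameters.

    ``beta`` applies to ``interaction4`` only; ``n_noise_loci``,
    ``heritability_noise`` and ``maf`` apply to ``epistasis`` only.
    """

    dgp_id: DGP
    n: int
    seed: int = 0
    beta: float = 0.0
    n_noise_loci: int = 0
    heritability_noise: float = 0.0
    maf: float = EPISTASIS_MAF

    def __post_init__(self) -> None:
        object.__setattr__(self, "dgp_id", DGP(self.dgp_id))
        if self.n < 1:
            raise InvalidArgumentError("n must be >= 1")
        if not np.isfinite(self.beta):
            raise InvalidArgumentError("beta must be finite")
        if self.n_noise_loci < 0:
            raise InvalidArgumentError("n_noise_loci must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["dgp_id"] = self.dgp_id.value
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DGPConfig":
        return cls(**json.loads(text))


def _check_n(n: int) -> None:
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")


# ---------------------------------------------------------------------------
# Label rules, exposed separately so tests can evaluate them with the noise
# term forced to zero.

def linear_labels(x: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Y = 1{3*X1 + eps > 0}."""
    return (3.0 * x + eps > 0).astype(np.int64)


def interval_labels(x: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Y = 1{X1 + 0.25*eps in (-6, -2.5) u (0, 1.5)}."""
    z = x + 0.25 * eps
    return (((z > -6.0) & (z < -2.5)) | ((z > 0.0) & (z < 1.5))).astype(np.int64)


def interaction_labels(X: np.ndarray, beta: float) -> np.ndarray:
    """Y = 1{sigma(sum_i X_i + beta*X3*X4) > 0.5} = 1{sum_i X_i + beta*X3*X4 > 0}.

    The logistic function exceeds 1/2 exactly when its argument is positive,
    so given the drawn predictors the label is deterministic.
    """
    z = X.sum(axis=1) + beta * X[:, 2] * X[:, 3]
    return (z > 0).astype(np.int64)


def xor_labels(genotypes: np.ndarray) -> np.ndarray:
    """Trait = 1 iff exactly one of the two causal loci carries a minor allele."""
    c1 = genotypes[:, 0] >= 1
    c2 = genotypes[:, 1] >= 1
    return (c1 ^ c2).astype(np.int64)


# ---------------------------------------------------------------------------
# Generators.

def _logistic_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    # inverse-CDF transform of U(0,1): quantile of the standard logistic
    u = rng.uniform(size=n)
    return np.log(u / (1.0 - u))


def gen_linear_dgp(n: int, seed: int, include_noise: bool = True) -> LabeledDataset:
    """One-predictor linear-logit process: Y = 1{3*X1 + eps > 0}.

    ``X1 ~ N(0,1)``, ``eps ~ Logistic(0,1)``; hence P(Y=1 | X1=x) = sigma(3x).
    ``include_noise=False`` zeroes the noise term (testing aid).
    """
    _check_n(n)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eps = _logistic_noise(rng, n) if include_noise else np.zeros(n)
    return LabeledDataset(x.reshape(-1, 1), linear_labels(x, eps), ("X1",))


def gen_nonlinear_dgp(n: int, seed: int, include_noise: bool = True) -> LabeledDataset:
    """Interval-membership process: Y = 1{X1 + 0.25*eps in (-6,-2.5) u (0,1.5)}."""
    _check_n(n)
    rng = np.random.default_rng(seed)
    x = rng.uniform(-10.0, 10.0, size=n)
    eps = rng.normal(size=n) if include_noise else np.zeros(n)
    return LabeledDataset(x.reshape(-1, 1), interval_labels(x, eps), ("X1",))


def gen_interaction_dgp(n: int, beta: float, seed: int) -> LabeledDataset:
    """Four-predictor process with a beta-scaled product interaction.

    ``X1..X3 ~ N(0,1)`` and ``X4`` takes the values -0.5 and +0.5 with equal
    probability. Labels are ``1{X1+X2+X3+X4 + beta*X3*X4 > 0}`` (see
    :func:`interaction_labels` for why no extra noise term appears).
    """
    _check_n(n)
    if not np.isfinite(beta):
        raise InvalidArgumentError("beta must be finite")
    rng = np.random.default_rng(seed)
    X = np.empty((n, 4))
    X[:, :3] = rng.normal(size=(n, 3))
    X[:, 3] = rng.choice((-0.5, 0.5), size=n)
    return LabeledDataset(X, interaction_labels(X, beta), ("X1", "X2", "X3", "X4"))


def gen_epistasis_dgp(
    n: int,
    n_noise_loci: int = 18,
    heritability_noise: float = 0.1,
    seed: int = 0,
    maf: float = EPISTASIS_MAF,
) -> LabeledDataset:
    """Two-locus XOR-penetrance trait with additional non-causal loci.

    Genotypes at every locus are ``Binomial(2, maf)`` counts of the minor
    allele (Hardy–Weinberg equilibrium). The trait is the XOR of the two
    causal carrier indicators, then flipped with probability
    ``heritability_noise`` (incomplete penetrance / phenocopies). At the
    default ``maf = 1 - 1/sqrt(2)`` the carrier probability is exactly 1/2,
    so both causal loci have zero marginal association with the trait.
    """
    _check_n(n)
    if not 0.0 <= heritability_noise <= 0.5:
        raise InvalidArgumentError(
            f"heritability_noise must lie in [0, 0.5], got {heritability_noise}"
        )
    if not 0.0 < maf < 1.0:
        raise InvalidArgumentError("maf must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = 2 + n_noise_loci
    G = rng.binomial(2, maf, size=(n, p)).astype(float)
    y = xor_labels(G)
    if heritability_noise > 0:
        flip = rng.uniform(size=n) < heritability_noise
        y = np.where(flip, 1 - y, y)
    names = ("causal_a", "causal_b") + tuple(
        f"noise_{i + 1:02d}" for i in range(n_noise_loci)
    )
    return LabeledDataset(G, y, names)


def generate(config: DGPConfig) -> LabeledDataset:
    """Dispatch on :class:`DGPConfig`."""
    if config.dgp_id is DGP.linear:
        return gen_linear_dgp(config.n, config.seed)
    if config.dgp_id is DGP.nonlinear_interval:
        return gen_nonlinear_dgp(config.n, config.seed)
    if config.dgp_id is DGP.interaction4:
        return gen_interaction_dgp(config.n, config.beta, config.seed)
    if config.dgp_id is DGP.epistasis:
        return gen_epistasis_dgp(
            config.n,
            config.n_noise_loci,
            config.heritability_noise,
            config.seed,
            config.maf,
        )
    raise InvalidArgumentError(f"unknown DGP {config.dgp_id!r}")
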