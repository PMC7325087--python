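"""Tabular container for labeled binary-outcome data and its CSV round-trip.

The whole package operates on one unit: a numeric design matrix ``X`` of
shape (n, p), a binary outcome ``y`` in {0, 1}, and ``p`` unique predictor
names. Datasets are exchanged on disk as plain CSV with a header row, the
outcome stored in a column named ``"y"`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SchemaError

__all__ = ["LabeledDataset", "read_dataset", "write_dataset"]


@dataclass(frozen=True)
class LabeledDataset:
    """Design matrix plus binary outcome.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric predictor matrix; no missing values allowed.
    y : ndarray of shape (n,)
        Binary outcome coded 0/1.
    names : tuple of str
        One unique label per predictor column.
    """

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be a 2-D matrix")
        if y.shape != (X.shape[0],):
            raise InvalidArgumentError(
                f"y has shape {y.shape}, expected ({X.shape[0]},)"
            )
        names = tuple(self.names) if self.names else tuple(
            f"X{i + 1}" for i in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise SchemaError(
                f"{len(names)} names for {X.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise SchemaError("predictor names must be unique")
        if not np.all(np.isfinite(X)):
            raise InvalidArgumentError("X contains missing or non-finite values")
        if not np.isin(y, (0, 1)).all():
            raise InvalidArgumentError("y must contain only 0 and 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df["y"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str = "y") -> "LabeledDataset":
        if outcome not in df.columns:
            raise SchemaError(f"outcome column {outcome!r} not found")
        names = tuple(c for c in df.columns if c != outcome)
        return cls(df[list(names)].to_numpy(dtype=float), df[outcome].to_numpy(), names)


def read_dataset(path, outcome: str = "y") -> LabeledDataset:
    """Read a labeled dataset from a CSV file with a header row.

    Missing or non-numeric cells are rejected with the offending row and
    column named in the error message.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: header only, no data rows")
    if outcome not in df.columns:
        raise SchemaError(f"{path}: outcome column {outcome!r} not found")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric or missing value at row {row}, column {col!r}"
            )
        df[col] = numeric
    return LabeledDataset.from_frame(df, outcome=outcome)


def write_dataset(data: LabeledDataset, path) -> None:
    """Write a dataset to CSV (header row, outcome in column ``y``)."""
    data.to_frame().to_csv(path, index=False)
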