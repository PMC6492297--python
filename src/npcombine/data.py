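"""Domain containers for replication/trait matrices and their validation.

A *replication matrix* ``Y`` holds, for each of N subjects, R noisy
estimates of the same unobserved subject-level quantity (e.g. repeated
Fisher-z functional-connectivity estimates, or per-run summaries of a
stochastic inference algorithm).  A *trait matrix* ``X`` holds the P
observed subject variables tested against ``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReplicationMatrix",
    "TraitMatrix",
    "DegenerateColumnError",
    "DimensionMismatchError",
]


class DegenerateColumnError(ValueError):
    """A column is constant (zero variance), so a correlation test is undefined."""


class DimensionMismatchError(ValueError):
    """Subject counts (or other shared dimensions) do not agree."""


def _check_columns(values: np.ndarray, ids: list[str], what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite values")
    sd = values.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(str(ids[i]) for i in bad[:5])
        raise DegenerateColumnError(
            f"{what} has constant column(s) with zero variance: {names}"
        )


def _as_ids(ids, n: int, prefix: str) -> list[str]:
    if ids is None:
        return [f"{prefix}{i}" for i in range(n)]
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValueError(f"expected {n} labels, got {len(ids)}")
    return ids


@dataclass
class ReplicationMatrix:
    """N x R matrix of per-subject replication values.

    Parameters
    ----------
    values
        Real matrix, one row per subject, one column per replication.
    subject_ids, replication_ids
        Optional labels; generated as ``s0..`` / ``rep0..`` when omitted.
    """

    values: np.ndarray
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]
    replication_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("replication matrix must be 2-D (subjects x replications)")
        n, r = self.values.shape
        if n < 3:
            raise ValueError(
                "need at least 3 subjects (the first-level correlation test has N-2 df)"
            )
        self.subject_ids = _as_ids(self.subject_ids, n, "s")
        self.replication_ids = _as_ids(self.replication_ids, r, "rep")
        _check_columns(self.values, self.replication_ids, "replication matrix")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_replications(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ReplicationMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=list(df.index.astype(str)),
            replication_ids=list(df.columns.astype(str)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.replication_ids
        )


@dataclass
class TraitMatrix:
    """N x P matrix of observed subject variables (traits)."""

    values: np.ndarray
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]
    variable_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("trait matrix must be 2-D (subjects x variables)")
        n, p = self.values.shape
        self.subject_ids = _as_ids(self.subject_ids, n, "s")
        self.variable_ids = _as_ids(self.variable_ids, p, "var")
        _check_columns(self.values, self.variable_ids, "trait matrix")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=list(df.index.astype(str)),
            variable_ids=list(df.columns.astype(str)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.variable_ids
        )


def check_matched(Y: ReplicationMatrix, X: TraitMatrix) -> None:
    """Raise if the two matrices do not describe the same subjects."""
    if Y.n_subjects != X.n_subjects:
        raise DimensionMismatchError(
            f"replication matrix has {Y.n_subjects} subjects, "
            f"trait matrix has {X.n_subjects}"
        )
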