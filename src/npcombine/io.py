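"""Delimited-text input/output.

Matrices travel as CSV/TSV with one header row and a leading subject-ID
column; exchangeability blocks as a two-column table (subject_id,
block_label).  Results are written as TSV with full double precision.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import ReplicationMatrix, TraitMatrix

__all__ = [
    "read_replications",
    "read_traits",
    "read_blocks",
    "write_matrix",
    "write_result_table",
]


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return df


def read_replications(path: str | os.PathLike) -> ReplicationMatrix:
    return ReplicationMatrix.from_dataframe(_read_table(path))


def read_traits(path: str | os.PathLike) -> TraitMatrix:
    return TraitMatrix.from_dataframe(_read_table(path))


def read_blocks(path: str | os.PathLike, subject_ids: list[str]) -> np.ndarray:
    """Read block labels and align them to the given subject order."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (subject_id, block_label)")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
    missing = [s for s in subject_ids if s not in mapping]
    if missing:
        raise ValueError(f"{path}: no block label for subject(s) {missing[:5]}")
    return np.asarray([mapping[s] for s in subject_ids])


def write_matrix(
    values: np.ndarray,
    path: str | os.PathLike,
    index: list[str],
    columns: list[str],
    index_label: str = "subject_id",
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(np.asarray(values), index=index, columns=columns).to_csv(
        path, sep=sep, index_label=index_label, float_format="%.17g"
    )


def write_result_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
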