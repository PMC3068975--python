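"""Tabular input and JSON-friendly serialisation helpers."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["read_table", "as_fraction_or_percent"]

log = logging.getLogger("roctools")


def read_table(
    path,
    response_col: str,
    predictor_cols: Sequence[str],
    positive_label=None,
    sep: Optional[str] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a CSV/TSV with one response column and one or more predictors.

    Rows with a missing response or any missing requested predictor are
    dropped (the count is logged).  The separator is inferred from the file
    extension unless given (.tsv/.txt -> tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in [response_col, *predictor_cols] if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"column(s) {missing} not found; available: {list(df.columns)}"
        )
    used = df[[response_col, *predictor_cols]]
    keep = used.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d row(s) with missing values", dropped)
    used = used[keep]
    if used.empty:
        raise InvalidInputError("no complete rows after dropping missing values")
    response = used[response_col].to_numpy()
    if np.unique(response).size < 2:
        raise InvalidInputError("response has fewer than 2 distinct labels")
    predictors = used[list(predictor_cols)].apply(pd.to_numeric)
    return response, predictors


def as_fraction_or_percent(value: float, percent: bool) -> float:
    """Scale a rate for display; storage is always a fraction."""
    return value * 100.0 if percent else value
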