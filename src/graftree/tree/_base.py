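"""Common plumbing for the tree learners: column preparation, routing with
a majority-direction fallback for missing values, and parameter containers."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("graftree")

__all__ = ["TreeParams", "prepare_columns", "route_rows"]


@dataclass(frozen=True)
class TreeParams:
    """Hyperparameters shared by the survival and classification trees.

    cp:
        complexity parameter on the rpart-style relative scale: a split must
        improve the fit by at least ``cp`` times the root deviance/impurity
        to survive pruning. Negative values disable pruning entirely.
    maxdepth, minsplit, minbucket:
        depth bound, minimum subjects to attempt a split, and minimum
        subjects per child.
    """

    cp: float = -1.0
    maxdepth: int = 6
    minsplit: int = 20
    minbucket: int = 7

    def __post_init__(self):
        if self.maxdepth < 1:
            raise ValueError("maxdepth must be >= 1")
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if self.minsplit < 2 * self.minbucket:
            raise ValueError("minsplit must be >= 2 * minbucket")
        if not np.isfinite(self.cp):
            raise ValueError("cp must be finite")


def prepare_columns(X):
    """Split a DataFrame/array into per-feature 1-D arrays plus kind labels.

    Numeric (and boolean) columns become ordered covariates; object and
    pandas-categorical columns become categorical ones.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        columns, kinds = [], []
        for c in names:
            col = X[c]
            if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
                columns.append(col.to_numpy(dtype=float))
                kinds.append("ordered")
            else:
                columns.append(col.to_numpy(dtype=object))
                kinds.append("categorical")
        return columns, kinds, names
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if arr.dtype == object:
        columns, kinds = [], []
        for j in range(arr.shape[1]):
            col = arr[:, j]
            try:
                columns.append(col.astype(float))
                kinds.append("ordered")
            except (TypeError, ValueError):
                columns.append(col)
                kinds.append("categorical")
    else:
        columns = [arr[:, j].astype(float) for j in range(arr.shape[1])]
        kinds = ["ordered"] * arr.shape[1]
    return columns, kinds, [f"x{j}" for j in range(arr.shape[1])]


def _is_missing(x):
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def route_rows(node, columns, idx):
    """Partition row indices at ``node``'s split; missing values follow the
    majority direction recorded at fit time (logged, since fully imputed
    inputs should never hit this path)."""
    x = columns[node.split.feature][idx]
    left = node.split.goes_left(x)
    if node.split.is_categorical:
        known = np.fromiter((not _is_missing(v) for v in x), dtype=bool, count=len(x))
    else:
        known = ~np.isnan(np.asarray(x, dtype=float))
    n_miss = int((~known).sum())
    if n_miss:
        logger.warning(
            "routing %d row(s) with missing %r by majority direction (%s)",
            n_miss,
            node.split.feature,
            "left" if node.majority_left else "right",
        )
        left = np.where(known, left, node.majority_left)
    return idx[left], idx[~left]
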