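"""Shared recursive-partitioning split search.

All tree learners in this package (Poisson-deviance survival trees, weighted
Gini classification trees, and the CART conditional models used for chained
imputation) reduce their split criterion to the same computation: sort the
rows of one covariate, accumulate per-row sufficient statistics with a prefix
sum, and score every admissible cut with a criterion-specific gain function on
the unnormalised sums. This module implements that engine once.

Conventions, chosen for cross-platform determinism:

* candidate cuts for ordered covariates are midpoints between consecutive
  distinct observed values;
* categorical covariates are ordered by a criterion-specific per-level key
  (event rate, positive fraction, or mean) and scanned as if ordered, which is
  exact for one-dimensional sufficient statistics;
* ties in gain are broken toward the lowest covariate index, then the lowest
  threshold (or smallest left category set in scan order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplitCandidate", "find_best_split", "GAIN_EPS"]

#: relative tolerance below which a gain is treated as zero (guards against
#: analytically-null splits surfacing as 1e-16 float noise on pure nodes)
GAIN_EPS = 1e-10


@dataclass(frozen=True)
class SplitCandidate:
    """One binary split: ``feature`` goes left when ``x <= threshold`` for
    ordered covariates, or ``x in left_categories`` for categorical ones."""

    feature: int
    threshold: float | None
    left_categories: frozenset | None
    gain: float

    @property
    def is_categorical(self) -> bool:
        return self.left_categories is not None

    def goes_left(self, x: np.ndarray) -> np.ndarray:
        """Vectorised routing; NaN rows come back False (caller handles)."""
        if self.is_categorical:
            return np.isin(np.asarray(x, dtype=object), list(self.left_categories))
        with np.errstate(invalid="ignore"):
            return np.asarray(x, dtype=float) <= self.threshold


def _scan_ordered(x, stats, gain_fn, total, min_bucket):
    """Score all midpoint cuts of an ordered covariate; return (gain, thr)."""
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    distinct = xs[:-1] < xs[1:]
    if not distinct.any():
        return None
    cum = np.cumsum(stats[order], axis=0)[:-1]
    counts = cum[:, -1]
    total_count = stats[:, -1].sum()
    valid = distinct & (counts >= min_bucket) & (total_count - counts >= min_bucket)
    if not valid.any():
        return None
    gains = gain_fn(cum, total)
    gains = np.where(valid, gains, -np.inf)
    i = int(np.argmax(gains))  # first max -> lowest threshold
    return float(gains[i]), float((xs[i] + xs[i + 1]) / 2.0)


def _scan_categorical(x, stats, gain_fn, level_key_fn, total, min_bucket):
    """Order levels by the criterion key, scan prefixes; return (gain, cats)."""
    codes, levels = _factorize(x)
    k = len(levels)
    if k < 2:
        return None
    lev_stats = np.zeros((k, stats.shape[1]))
    np.add.at(lev_stats, codes, stats)
    keys = level_key_fn(lev_stats)
    order = np.lexsort((np.arange(k), keys))  # stable: level order breaks key ties
    cum = np.cumsum(lev_stats[order], axis=0)[:-1]
    counts = cum[:, -1]
    valid = (counts >= min_bucket) & (total[-1] - counts >= min_bucket)
    if not valid.any():
        return None
    gains = gain_fn(cum, total)
    gains = np.where(valid, gains, -np.inf)
    i = int(np.argmax(gains))
    cats = frozenset(levels[order[: i + 1]].tolist())
    return float(gains[i]), cats


def _factorize(x):
    """Deterministic integer coding of a categorical column (sorted levels)."""
    arr = np.asarray(x, dtype=object)
    levels = np.array(sorted(set(arr.tolist()), key=str), dtype=object)
    lookup = {v: i for i, v in enumerate(levels.tolist())}
    codes = np.fromiter((lookup[v] for v in arr.tolist()), dtype=np.intp, count=len(arr))
    return codes, levels


def find_best_split(
    columns,
    kinds,
    stats,
    gain_fn,
    level_key_fn,
    min_bucket,
    feature_indices,
):
    """Return the best :class:`SplitCandidate` with strictly positive gain.

    Parameters
    ----------
    columns : sequence of 1-D arrays, one per covariate (node rows only).
    kinds : sequence of {"ordered", "categorical"} per covariate.
    stats : (n_rows, n_stats) float array of per-row sufficient statistics;
        the LAST column is each row's size contribution (ones for subject
        counts, weights for weighted instance sets) — ``min_bucket`` bounds
        its per-child sum.
    gain_fn : maps (cumulative left stats (m, n_stats), total stats) to an
        unnormalised gain vector of length m; larger is better.
    level_key_fn : maps per-level stats (k, n_stats) to a sort key per level.
    min_bucket : minimum subjects per child.
    feature_indices : covariate indices to search, scanned in the given order
        (pass a subset for random-forest node sampling).
    """
    total = stats.sum(axis=0)
    scale = max(1.0, float(np.abs(total[:-1]).max(initial=0.0)))
    best: SplitCandidate | None = None
    for j in feature_indices:
        x = columns[j]
        if kinds[j] == "categorical":
            res = _scan_categorical(x, stats, gain_fn, level_key_fn, total, min_bucket)
            if res is None:
                continue
            g, cats = res
            cand = SplitCandidate(int(j), None, cats, g)
        else:
            res = _scan_ordered(
                np.asarray(x, dtype=float), stats, gain_fn, total, min_bucket
            )
            if res is None:
                continue
            g, thr = res
            cand = SplitCandidate(int(j), thr, None, g)
        if g <= GAIN_EPS * scale:
            continue
        if best is None or cand.gain > best.gain:
            best = cand
    return best
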