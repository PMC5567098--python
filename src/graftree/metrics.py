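"""Model assessment: Harrell's concordance, weighted AUC, Kaplan-Meier and
event-stratified partitioning.

Harrell's C is computed with the conventions spelled out below (the pairwise
definitions differ subtly between implementations): a pair is comparable when
the strictly smaller observation time carries an event; ties in time are not
comparable; tied risk scores count one half. The partitioner stratifies every
split and fold on the event indicator so the ~10% event fraction survives
subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "UndefinedMetricError",
    "concordance_index",
    "weighted_auc",
    "KMCurve",
    "km_estimator",
    "SplitPlan",
    "PartitionSet",
    "make_partitions",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (no comparable pairs,
    single-class input, ...) rather than silently returning a number."""


def concordance_index(times, events, risks) -> float:
    """Harrell's concordance index of a risk score against censored outcomes.

    Comparable pairs are those where the smaller time carries an event;
    the pair is concordant when that subject also has the larger risk; tied
    risks score 0.5; time ties (including double events) are not comparable.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risks, dtype=float)
    if not (t.shape == e.shape == r.shape):
        raise ValueError("times, events and risks must have equal length")
    if not (t > 0).all():
        raise ValueError("times must be positive")
    # comparable[i, j]: t_i < t_j and subject i had the event
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs (all ties or no events)")
    greater = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    num = float((comparable & greater).sum()) + 0.5 * float((comparable & tied).sum())
    return num / n_comp


def weighted_auc(labels, scores, weights=None) -> float:
    """Weighted Mann-Whitney AUC; ties count 0.5; weights default to 1."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if not (y.shape == s.shape == w.shape):
        raise ValueError("labels, scores and weights must have equal length")
    pos = y == 1
    neg = y == 0
    wp, wn = w[pos], w[neg]
    if wp.sum() <= 0 or wn.sum() <= 0:
        raise UndefinedMetricError("both classes need positive total weight")
    sp, sn = s[pos], s[neg]
    gt = (sp[:, None] > sn[None, :]).astype(float)
    eq = (sp[:, None] == sn[None, :]).astype(float)
    pair_w = wp[:, None] * wn[None, :]
    return float((pair_w * (gt + 0.5 * eq)).sum() / pair_w.sum())


class KMCurve:
    """Right-continuous Kaplan-Meier survivor step function, ``S(0) = 1``."""

    def __init__(self, times, events):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        if t.size == 0:
            raise ValueError("km_estimator requires at least one observation")
        if not (t > 0).all():
            raise ValueError("times must be positive")
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        sf = kmf.survival_function_
        self.grid_ = sf.index.to_numpy(dtype=float)
        self.surv_ = sf.iloc[:, 0].to_numpy(dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.grid_, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.grid_) - 1)
        out = np.where(t < self.grid_[0], 1.0, self.surv_[idx])
        return float(out) if out.ndim == 0 else out


def km_estimator(times, events) -> KMCurve:
    """Product-limit survivor estimate as a callable step function."""
    return KMCurve(times, events)


@dataclass(frozen=True)
class SplitPlan:
    """Holdout + inner-validation layout of one protocol row.

    Exactly one of ``n_folds`` (cross-validation) and ``validation_ratio``
    (one-validation) must be set, matching ``validation_method``. All splits
    stratify on the event indicator. Defaults follow the published protocol
    tables: test ratio 0.3 with 5-fold inner cross-validation.
    """

    test_ratio: float = 0.3
    validation_method: str = "cross-validation"  # or "one-validation"
    n_folds: int | None = 5
    validation_ratio: float | None = None
    stratify_on: str = "event"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_ratio < 1:
            raise ValueError("test_ratio must be in (0, 1)")
        if self.validation_method == "cross-validation":
            if self.n_folds is None or self.validation_ratio is not None:
                raise ValueError("cross-validation requires n_folds and no validation_ratio")
            if self.n_folds < 2:
                raise ValueError("n_folds must be >= 2")
        elif self.validation_method == "one-validation":
            if self.validation_ratio is None or self.n_folds is not None:
                raise ValueError("one-validation requires validation_ratio and no n_folds")
            if not 0 < self.validation_ratio < 1:
                raise ValueError("validation_ratio must be in (0, 1)")
        else:
            raise ValueError("validation_method must be 'cross-validation' or 'one-validation'")


@dataclass
class PartitionSet:
    """Train/test indices plus the inner validation layout.

    ``folds`` is a list of (fit_idx, val_idx) pairs: ``n_folds`` of them for
    cross-validation, a single pair for one-validation (the validation ratio
    is taken as a fraction of the non-test data).
    """

    train: np.ndarray
    test: np.ndarray
    folds: list


def _stratified_take(idx_by_class, fraction, rng):
    """Draw round(fraction * n) per class (half away from zero)."""
    taken, kept = [], []
    for cls_idx in idx_by_class:
        perm = cls_idx[rng.permutation(len(cls_idx))]
        k = int(np.floor(fraction * len(cls_idx) + 0.5))
        taken.append(perm[:k])
        kept.append(perm[k:])
    return np.sort(np.concatenate(taken)), np.sort(np.concatenate(kept))


def make_partitions(cohort, plan: SplitPlan) -> PartitionSet:
    """Event-stratified train/test split plus inner folds, deterministic per
    ``plan.seed``."""
    strat = (cohort.event if plan.stratify_on == "event"
             else np.asarray(cohort.data[plan.stratify_on]))
    strat = np.asarray(strat)
    classes = np.unique(strat)
    rng = np.random.default_rng(plan.seed)
    idx_by_class = [np.flatnonzero(strat == c) for c in classes]
    test, train = _stratified_take(idx_by_class, plan.test_ratio, rng)

    train_by_class = [train[strat[train] == c] for c in classes]
    if plan.validation_method == "one-validation":
        val, fit = _stratified_take(train_by_class, plan.validation_ratio, rng)
        folds = [(fit, val)]
    else:
        k = plan.n_folds
        if any(len(ci) < k for ci in train_by_class):
            raise ValueError(
                f"n_folds={k} exceeds the size of a stratification class in the training set"
            )
        assignments = np.empty(len(strat), dtype=int)
        for ci in train_by_class:
            perm = ci[rng.permutation(len(ci))]
            assignments[perm] = np.arange(len(perm)) % k
        folds = []
        for f in range(k):
            val = np.sort(train[assignments[train] == f])
            fit = np.sort(train[assignments[train] != f])
            folds.append((fit, val))
    return PartitionSet(train=train, test=test, folds=folds)
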