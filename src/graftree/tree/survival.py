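"""Survival decision tree with a Poisson event-rate/deviance split rule.

Each node summarises its subjects by the observed event rate
``lambda = sum(c_i) / sum(t_i)`` (events per month, with ``c_i`` the 0/1
graft-failure indicator and ``t_i`` the observation time), and by the
within-node deviance

``D = (1/N) * sum_i [ c_i * log(c_i / (lambda * t_i)) - (c_i - lambda * t_i) ]``

with the convention ``0 * log 0 = 0``. Splits maximise the deviance
improvement ``D_parent - (D_left + D_right)``. Because a uniform ``1/N``
factor would make the improvement depend on how the normalisation is read,
the split search and pruning operate on the unnormalised sums (the Sigma
form, for which the improvement is the Poisson log-likelihood-ratio statistic
and provably nonnegative); the per-subject ``D`` is kept on every node for
reporting. Leaves predict a hazard ratio: node rate divided by root rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .._split import SplitCandidate, find_best_split
from ._base import TreeParams, logger, prepare_columns, route_rows

__all__ = [
    "SurvivalNode",
    "SurvivalTree",
    "node_stats",
    "best_split",
    "grow_tree",
    "prune_tree",
    "predict_hr",
]


def node_stats(events, times, weights=None):
    """Observed event rate and within-node deviance of one node.

    Returns ``(rate, deviance)`` where ``rate = sum(c)/sum(t)`` and
    ``deviance`` is the per-subject (1/N-normalised) Poisson deviance; both
    use ``0*log(0) = 0``. Weights, when given, multiply each subject's
    contribution and replace N by the total weight.
    """
    c = np.asarray(events, dtype=float)
    t = np.asarray(times, dtype=float)
    if c.size == 0:
        raise ValueError("node_stats requires at least one observation")
    if c.shape != t.shape:
        raise ValueError("events and times must have equal length")
    if not (t > 0).all():
        raise ValueError("all observation times must be positive")
    w = np.ones_like(c) if weights is None else np.asarray(weights, dtype=float)
    E = float(np.sum(w * c))
    T = float(np.sum(w * t))
    N = float(np.sum(w))
    rate = E / T if T > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(c, np.where(c > 0, c / (rate * t), 1.0)) - (c - rate * t)
    dev = float(np.sum(w * terms)) / N if N > 0 else 0.0
    return rate, max(dev, 0.0)


def _poisson_gain(cum, total):
    """Sigma-form deviance improvement at every cut. Within a node the
    linear deviance term vanishes and ``sum c log t`` is partition-invariant,
    so the improvement reduces to f(E_l,T_l) + f(E_r,T_r) - f(E_p,T_p) with
    f(E, T) = E log(E/T) on the children's event/time sums."""
    El, Tl = cum[:, 0], cum[:, 1]
    Ep, Tp = total[0], total[1]
    Er, Tr = Ep - El, Tp - Tl
    with np.errstate(divide="ignore", invalid="ignore"):
        f = lambda E, T: xlogy(E, E) - xlogy(E, T)  # noqa: E731
        return f(El, Tl) + f(Er, Tr) - f(Ep, Tp)


def _poisson_level_key(lev_stats):
    E, T = lev_stats[:, 0], lev_stats[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(T > 0, E / np.where(T > 0, T, 1.0), 0.0)


@dataclass
class SurvivalNode:
    """One node of the partition; ``hr`` is the node rate over the root rate."""

    n: int
    event_sum: float
    time_sum: float
    rate: float
    deviance: float
    hr: float = 1.0
    #: shrunken hazard ratio ((E + 1/2) / (T + (1/2)/rate_root)) / rate_root:
    #: strictly positive even for event-free leaves, so log-scale ensemble
    #: aggregation stays finite; reporting always uses the exact ``hr``
    hr_smooth: float = 1.0
    depth: int = 0
    split: SplitCandidate | None = None
    majority_left: bool = True
    improvement: float = 0.0
    left: "SurvivalNode | None" = None
    right: "SurvivalNode | None" = None
    warnings: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


class SurvivalTree:
    """Recursive-partitioning survival tree (scikit-learn style estimator).

    Parameters
    ----------
    cp : float, default -1.0
        Complexity parameter; a split survives only if its Sigma-form
        deviance improvement is at least ``cp`` times the root's Sigma-form
        deviance. Negative disables pruning (the tables' ``cp = -1``).
    maxdepth, minsplit, minbucket : int
        Growth controls, rpart-flavoured defaults.
    max_features : int or None
        When set, each node's split search samples this many covariates
        without replacement (random-forest node-level sampling).
    random_state : int, numpy Generator, or None
        Only consulted when ``max_features`` is set.

    Attributes
    ----------
    root_ : SurvivalNode
        Fitted partition; ``root_.hr == 1`` exactly.
    feature_names_in_ : list of str
    """

    def __init__(self, *, cp=-1.0, maxdepth=6, minsplit=20, minbucket=7,
                 max_features=None, random_state=None):
        self.cp = cp
        self.maxdepth = maxdepth
        self.minsplit = minsplit
        self.minbucket = minbucket
        self.max_features = max_features
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep=True):
        return dict(cp=self.cp, maxdepth=self.maxdepth, minsplit=self.minsplit,
                    minbucket=self.minbucket, max_features=self.max_features,
                    random_state=self.random_state)

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None, *, time=None, event=None, sample_weight=None):
        """Fit on covariates ``X`` and censored outcomes.

        Outcomes may be passed as a structured array ``y`` with fields
        ``event``/``time`` (scikit-survival convention) or as the ``time``
        and ``event`` keyword arrays.
        """
        time, event = _resolve_outcome(y, time, event)
        params = TreeParams(cp=self.cp, maxdepth=self.maxdepth,
                            minsplit=self.minsplit, minbucket=self.minbucket)
        columns, kinds, names = prepare_columns(X)
        n = len(time)
        if n == 0:
            raise ValueError("empty cohort")
        if any(len(col) != n for col in columns):
            raise ValueError("X and outcomes disagree on length")
        for j, (col, kind) in enumerate(zip(columns, kinds)):
            has_nan = (np.isnan(col).any() if kind == "ordered"
                       else any(v is None or v != v for v in col))
            if has_nan:
                raise ValueError(
                    f"covariate {names[j]!r} has missing values; impute or "
                    "drop incomplete rows before fitting"
                )
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        rng = None
        if self.max_features is not None:
            rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
                   else np.random.default_rng(self.random_state))

        t = np.asarray(time, dtype=float)
        c = np.asarray(event, dtype=float)
        if not (t > 0).all():
            raise ValueError("all observation times must be positive")
        stats = np.column_stack([w * c, w * t, np.ones(n)])

        self.warnings_: list[str] = []
        root = self._grow(np.arange(n), 0, columns, kinds, stats, c, t, w, params, rng)
        if root.event_sum == 0:
            msg = "cohort has zero events: root-only tree with rate 0"
            self.warnings_.append(msg)
            warnings.warn(msg, stacklevel=2)
        # Sigma-form root deviance = per-subject deviance times total weight
        self.root_dev_sigma_ = root.deviance * float(w.sum())
        if params.cp >= 0:
            root = _prune_node(root, params.cp * self.root_dev_sigma_)
        _set_hr(root, root.rate)
        root.hr = 1.0
        self.root_ = root
        self.feature_names_in_ = names
        self.kinds_ = kinds
        self.n_features_in_ = len(names)
        return self

    def _grow(self, idx, depth, columns, kinds, stats, c, t, w, params, rng):
        rate, dev = node_stats(c[idx], t[idx], w[idx])
        node = SurvivalNode(
            n=len(idx),
            event_sum=float(np.sum(w[idx] * c[idx])),
            time_sum=float(np.sum(w[idx] * t[idx])),
            rate=rate,
            deviance=dev,
            depth=depth,
        )
        if depth >= params.maxdepth - 1 or len(idx) < params.minsplit or node.event_sum == 0:
            return node
        feats = np.arange(len(columns))
        if rng is not None and self.max_features < len(columns):
            feats = np.sort(rng.choice(len(columns), size=self.max_features, replace=False))
        split = find_best_split(
            [col[idx] for col in columns], kinds, stats[idx],
            _poisson_gain, _poisson_level_key, params.minbucket, feats,
        )
        if split is None:
            return node
        node.split = split
        node.improvement = split.gain
        li, ri = route_rows(node, columns, idx)
        node.majority_left = len(li) >= len(ri)
        node.left = self._grow(li, depth + 1, columns, kinds, stats, c, t, w, params, rng)
        node.right = self._grow(ri, depth + 1, columns, kinds, stats, c, t, w, params, rng)
        return node

    # -- prediction ---------------------------------------------------------
    def predict(self, X):
        """Hazard ratio (leaf rate / root rate) for each row of ``X``."""
        return self._predict_attr(X, "hr")

    def _predict_attr(self, X, attr):
        _check_fitted(self)
        columns, _, names = prepare_columns(X)
        if len(columns) != self.n_features_in_:
            raise ValueError("X has a different number of covariates than at fit")
        n = len(columns[0]) if columns else 0
        out = np.empty(n, dtype=float)
        self._route(self.root_, columns, np.arange(n), out, attr)
        return out

    def _route(self, node, columns, idx, out, attr):
        if len(idx) == 0:
            return
        if node.is_leaf:
            out[idx] = getattr(node, attr)
            return
        li, ri = route_rows(node, columns, idx)
        self._route(node.left, columns, li, out, attr)
        self._route(node.right, columns, ri, out, attr)

    def prune(self, cp: float) -> "SurvivalTree":
        """Return a pruned copy (see :func:`prune_tree`)."""
        return prune_tree(self, cp)


def _set_hr(node, root_rate):
    if root_rate > 0:
        node.hr = node.rate / root_rate
        node.hr_smooth = ((node.event_sum + 0.5)
                          / (node.time_sum + 0.5 / root_rate)) / root_rate
    else:
        node.hr = node.hr_smooth = float("nan")
    if not node.is_leaf:
        _set_hr(node.left, root_rate)
        _set_hr(node.right, root_rate)


def _prune_node(node, threshold):
    """A split survives iff its Sigma-form improvement is at least the
    threshold (and strictly positive); failing splits drop their subtree."""
    if node.is_leaf:
        return node
    if node.improvement < threshold or node.improvement <= 0:
        node.split = None
        node.left = node.right = None
        node.improvement = 0.0
        return node
    node.left = _prune_node(node.left, threshold)
    node.right = _prune_node(node.right, threshold)
    return node


def _check_fitted(est):
    if not hasattr(est, "root_"):
        raise ValueError("estimator is not fitted; call fit first")


def _resolve_outcome(y, time, event):
    if y is not None:
        if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
            names = y.dtype.names
            if len(names) != 2:
                raise ValueError("structured y must have exactly (event, time) fields")
            ev = next((n for n in names if y.dtype[n].kind == "b"), None)
            if ev is None:
                ev = next(n for n in names if n.lower() in ("event", "status", "delta", "cens"))
            tm = next(n for n in names if n != ev)
            return np.asarray(y[tm], dtype=float), np.asarray(y[ev], dtype=float)
        if isinstance(y, tuple) and len(y) == 2:
            return np.asarray(y[0], dtype=float), np.asarray(y[1], dtype=float)
        raise ValueError("y must be a structured (event, time) array or (time, event) tuple")
    if time is None or event is None:
        raise ValueError("provide y or both time= and event=")
    return np.asarray(time, dtype=float), np.asarray(event, dtype=float)


# ---------------------------------------------------------------------------
# functional surface


def best_split(cohort_view, params: TreeParams | None = None, weights=None,
               feature_indices=None):
    """Best deviance-improvement split of one node, or None.

    ``cohort_view`` is anything with ``data``/``time``/``event`` (a Cohort or
    a slice of one). Candidate cuts are midpoints between consecutive
    distinct values; categorical levels are scanned in event-rate order.
    """
    params = params or TreeParams()
    columns, kinds, _ = prepare_columns(cohort_view.data)
    c = np.asarray(cohort_view.event, dtype=float)
    t = np.asarray(cohort_view.time, dtype=float)
    n = len(c)
    if n < params.minsplit:
        return None
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    stats = np.column_stack([w * c, w * t, np.ones(n)])
    feats = np.arange(len(columns)) if feature_indices is None else feature_indices
    return find_best_split(columns, kinds, stats, _poisson_gain,
                           _poisson_level_key, params.minbucket, feats)


def grow_tree(cohort, params: TreeParams | None = None, weights=None) -> SurvivalTree:
    """Grow (and, if ``params.cp >= 0``, prune) a survival tree on a Cohort."""
    params = params or TreeParams()
    est = SurvivalTree(cp=params.cp, maxdepth=params.maxdepth,
                       minsplit=params.minsplit, minbucket=params.minbucket)
    return est.fit(cohort.data, time=cohort.time, event=cohort.event,
                   sample_weight=weights)


def prune_tree(tree: SurvivalTree, cp: float) -> SurvivalTree:
    """Cost-complexity pruning on the rpart-style relative scale; negative
    ``cp`` returns an identical copy (pruning disabled)."""
    import copy

    _check_fitted(tree)
    if not np.isfinite(cp):
        raise ValueError("cp must be finite")
    out = copy.deepcopy(tree)
    out.cp = cp
    if cp < 0:
        return out
    root = out.root_
    dev_sigma = getattr(tree, "root_dev_sigma_", root.deviance * root.n)
    _prune_node(root, cp * dev_sigma)
    return out


def predict_hr(tree: SurvivalTree, row):
    """Hazard ratio of the leaf one covariate record routes to."""
    import pandas as pd

    if isinstance(row, dict):
        row = pd.DataFrame([row])
    elif isinstance(row, pd.Series):
        row = row.to_frame().T
    return float(tree.predict(row)[0])
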