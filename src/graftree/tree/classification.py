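"""Weighted Gini classification tree for N-year graft-failure labels.

A conventional CART-style binary classifier, except that every training
instance carries a nonnegative weight so the censoring-aware instance sets
(Kaplan-Meier/Zupan weighting, where one censored subject contributes a
weighted positive and a weighted negative copy) plug in directly. Splits
maximise the weighted Gini impurity decrease on unnormalised sums; leaves
report the weighted graft-failure fraction, which is also the predicted
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._split import SplitCandidate, find_best_split
from ._base import TreeParams, prepare_columns, route_rows

__all__ = ["ClassNode", "GiniTreeClassifier", "fit_cart", "predict_fraction"]


def _gini_gain(cum, total):
    """Unnormalised weighted Gini decrease for every cut position.

    With P1/W the positive/total weight left of the cut, the weighted
    impurity of a child is ``2 * P1 * P0 / W``; the gain is the parent
    impurity minus the children's (scale-invariant up to overall weight)."""
    P1l, Wl = cum[:, 0], cum[:, 1]
    P1p, Wp = total[0], total[1]
    P1r, Wr = P1p - P1l, Wp - Wl

    def imp(P1, W):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(W > 0, 2.0 * P1 * (W - P1) / np.where(W > 0, W, 1.0), 0.0)

    return imp(P1p, Wp) - imp(P1l, Wl) - imp(P1r, Wr)


def _gini_level_key(lev_stats):
    P1, W = lev_stats[:, 0], lev_stats[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(W > 0, P1 / np.where(W > 0, W, 1.0), 0.0)


@dataclass
class ClassNode:
    n: int
    weight: float
    fraction: float  # weighted share of label-1 instances
    gini: float
    depth: int = 0
    split: SplitCandidate | None = None
    majority_left: bool = True
    improvement: float = 0.0
    left: "ClassNode | None" = None
    right: "ClassNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


class GiniTreeClassifier:
    """Binary CART with instance weights (scikit-learn style estimator).

    Same hyperparameters as :class:`~graftree.tree.survival.SurvivalTree`,
    except that ``minsplit``/``minbucket`` bound total instance *weight*
    rather than row counts (identical for unit weights; a censoring-weighted
    subject split into two instances still counts once). ``cp`` prunes splits
    whose Gini decrease falls below ``cp`` times the root impurity.
    ``predict_proba``/``predict_fraction`` return the leaf's weighted
    positive fraction.
    """

    def __init__(self, *, cp=-1.0, maxdepth=6, minsplit=20, minbucket=7,
                 max_features=None, random_state=None):
        self.cp = cp
        self.maxdepth = maxdepth
        self.minsplit = minsplit
        self.minbucket = minbucket
        self.max_features = max_features
        self.random_state = random_state

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

    def fit(self, X, y, sample_weight=None):
        params = TreeParams(cp=self.cp, maxdepth=self.maxdepth,
                            minsplit=self.minsplit, minbucket=self.minbucket)
        columns, kinds, names = prepare_columns(X)
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        rng = None
        if self.max_features is not None:
            rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
                   else np.random.default_rng(self.random_state))
        # last stats column = weight: minsplit/minbucket bound child WEIGHT,
        # so a Zupan-weighted pair (summing to 1) counts as one subject
        stats = np.column_stack([w * y, w])
        root = self._grow(np.arange(n), 0, columns, kinds, stats, y, w, params, rng)
        if params.cp >= 0:
            _prune(root, params.cp * root.gini)
        self.root_ = root
        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        return self

    def _grow(self, idx, depth, columns, kinds, stats, y, w, params, rng):
        W = float(np.sum(w[idx]))
        P1 = float(np.sum(w[idx] * y[idx]))
        frac = P1 / W if W > 0 else 0.0
        node = ClassNode(n=len(idx), weight=W, fraction=frac,
                         gini=2.0 * P1 * (W - P1) / W if W > 0 else 0.0, depth=depth)
        if depth >= params.maxdepth - 1 or W < params.minsplit or frac in (0.0, 1.0):
            return node
        feats = np.arange(len(columns))
        if rng is not None and self.max_features < len(columns):
            feats = np.sort(rng.choice(len(columns), size=self.max_features, replace=False))
        split = find_best_split([col[idx] for col in columns], kinds, stats[idx],
                                _gini_gain, _gini_level_key, params.minbucket, feats)
        if split is None:
            return node
        node.split = split
        node.improvement = split.gain
        li, ri = route_rows(node, columns, idx)
        node.majority_left = len(li) >= len(ri)
        node.left = self._grow(li, depth + 1, columns, kinds, stats, y, w, params, rng)
        node.right = self._grow(ri, depth + 1, columns, kinds, stats, y, w, params, rng)
        return node

    def predict_fraction(self, X):
        """Weighted graft-failure fraction of the leaf each row reaches."""
        if not hasattr(self, "root_"):
            raise ValueError("estimator is not fitted; call fit first")
        columns, _, _ = prepare_columns(X)
        if len(columns) != self.n_features_in_:
            raise ValueError("X has a different number of covariates than at fit")
        n = len(columns[0]) if columns else 0
        out = np.empty(n, dtype=float)
        self._route(self.root_, columns, np.arange(n), out)
        return out

    def predict_proba(self, X):
        p = self.predict_fraction(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_fraction(X) >= 0.5).astype(int)

    def _route(self, node, columns, idx, out):
        if len(idx) == 0:
            return
        if node.is_leaf:
            out[idx] = node.fraction
            return
        li, ri = route_rows(node, columns, idx)
        self._route(node.left, columns, li, out)
        self._route(node.right, columns, ri, out)


def _prune(node, threshold):
    if node.is_leaf:
        return
    if node.improvement < threshold or node.improvement <= 0:
        node.split = None
        node.left = node.right = None
        node.improvement = 0.0
        return
    _prune(node.left, threshold)
    _prune(node.right, threshold)


def fit_cart(X, labels, weights=None, params: TreeParams | None = None) -> GiniTreeClassifier:
    """Fit a weighted Gini tree on a labelled (possibly weighted) instance set."""
    params = params or TreeParams()
    est = GiniTreeClassifier(cp=params.cp, maxdepth=params.maxdepth,
                             minsplit=params.minsplit, minbucket=params.minbucket)
    return est.fit(X, labels, sample_weight=weights)


def predict_fraction(tree: GiniTreeClassifier, row):
    import pandas as pd

    if isinstance(row, dict):
        row = pd.DataFrame([row])
    elif isinstance(row, pd.Series):
        row = row.to_frame().T
    return float(tree.predict_fraction(row)[0])
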