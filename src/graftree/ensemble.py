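"""Bagging and random-forest ensembles over the tree base learners.

Survival ensembles aggregate per-tree hazard ratios on the log scale (the
reported score is the geometric-mean HR, preserving the root-reference
semantics of a ratio); classification ensembles average leaf fractions, with
plurality vote available behind a flag. Random forests differ from bagging
only by sampling ``mtry`` covariates at every node. Per-tree randomness comes
from spawned substreams of one seed sequence, so growing B+1 trees leaves the
first B unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree._base import TreeParams
from .tree.classification import GiniTreeClassifier
from .tree.survival import SurvivalTree

__all__ = [
    "EnsembleParams",
    "SurvivalEnsemble",
    "ClassificationEnsemble",
    "fit_bagging",
    "fit_random_forest",
    "predict_ensemble",
]

_HR_FLOOR = 1e-6  # event-free leaves predict HR 0; floored before the log


@dataclass(frozen=True)
class EnsembleParams:
    """n_trees bootstrap trees; ``mtry=None`` searches all covariates
    (bagging), an integer samples that many per node (random forest)."""

    n_trees: int = 50
    mtry: int | None = None
    bootstrap: bool = True
    seed: int = 0
    base_params: TreeParams = field(default_factory=TreeParams)

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class _BaseEnsemble:
    def __init__(self, *, n_trees=50, mtry=None, bootstrap=True, random_state=0,
                 cp=-1.0, maxdepth=6, minsplit=20, minbucket=7):
        self.n_trees = n_trees
        self.mtry = mtry
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.cp = cp
        self.maxdepth = maxdepth
        self.minsplit = minsplit
        self.minbucket = minbucket

    def get_params(self, deep=True):
        return dict(n_trees=self.n_trees, mtry=self.mtry, bootstrap=self.bootstrap,
                    random_state=self.random_state, cp=self.cp, maxdepth=self.maxdepth,
                    minsplit=self.minsplit, minbucket=self.minbucket)

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _tree_kwargs(self):
        return dict(cp=self.cp, maxdepth=self.maxdepth,
                    minsplit=self.minsplit, minbucket=self.minbucket)

    def _resamples(self, n):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and not 1 <= self.mtry:
            raise ValueError("mtry must be >= 1")
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            boot = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            oob = np.setdiff1d(np.arange(n), boot)
            yield boot, oob, rng


class SurvivalEnsemble(_BaseEnsemble):
    """Bagged (or node-randomized) Poisson-deviance survival trees.

    Attributes: ``trees_``, ``oob_indices_`` (per-tree out-of-bag rows),
    ``feature_importances_`` (total deviance improvement per covariate,
    summed over trees and normalised to 1).
    """

    def fit(self, X, y=None, *, time=None, event=None):
        from .tree.survival import _resolve_outcome

        t, e = _resolve_outcome(y, time, event)
        import pandas as pd

        Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        n = len(t)
        if self.mtry is not None and self.mtry > Xf.shape[1]:
            raise ValueError("mtry cannot exceed the number of covariates")
        self.trees_ = []
        self.oob_indices_ = []
        for boot, oob, rng in self._resamples(n):
            tree = SurvivalTree(max_features=self.mtry, random_state=rng,
                                **self._tree_kwargs())
            tree.fit(Xf.iloc[boot], time=t[boot], event=e[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        self.feature_names_in_ = list(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        self._X_fit, self._t_fit, self._e_fit = Xf, t, e
        imp = np.zeros(self.n_features_in_)
        for tree in self.trees_:
            _accumulate_importance(tree.root_, imp)
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def predict(self, X):
        """Geometric-mean hazard ratio over the trees.

        Event-free leaves carry an exact HR of 0, whose log would swamp the
        average; those predictions are replaced by the leaf's shrunken
        ``hr_smooth`` before taking logs."""
        if not self.trees_:
            raise ValueError("empty ensemble")
        logs = np.stack([np.log(self._tree_hr(tr, X)) for tr in self.trees_])
        return np.exp(logs.mean(axis=0))

    @staticmethod
    def _tree_hr(tree, X):
        hr = tree.predict(X)
        if (hr <= 0).any():
            smooth = tree._predict_attr(X, "hr_smooth")
            hr = np.where(hr > 0, hr, np.maximum(smooth, _HR_FLOOR))
        return hr

    def oob_predict(self):
        """Per-row geometric-mean HR over the trees that did not see the row;
        rows in every bootstrap sample come back NaN."""
        n = len(self._t_fit)
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if len(oob) == 0:
                continue
            pred = self._tree_hr(tree, self._X_fit.iloc[oob])
            acc[oob] += np.log(pred)
            cnt[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, np.exp(acc / np.maximum(cnt, 1)), np.nan)

    def oob_concordance(self):
        from .metrics import concordance_index

        risk = self.oob_predict()
        keep = ~np.isnan(risk)
        return concordance_index(self._t_fit[keep], self._e_fit[keep], risk[keep])


class ClassificationEnsemble(_BaseEnsemble):
    """Bagged weighted-Gini trees; aggregation is the average leaf fraction
    (``vote=True`` switches to plurality vote over 0.5-thresholded trees)."""

    def __init__(self, *, vote=False, **kwargs):
        super().__init__(**kwargs)
        self.vote = vote

    def get_params(self, deep=True):
        return dict(vote=self.vote, **super().get_params(deep))

    def fit(self, X, y, sample_weight=None):
        import pandas as pd

        Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        if self.mtry is not None and self.mtry > Xf.shape[1]:
            raise ValueError("mtry cannot exceed the number of covariates")
        self.trees_ = []
        self.oob_indices_ = []
        for boot, oob, rng in self._resamples(len(y)):
            tree = GiniTreeClassifier(max_features=self.mtry, random_state=rng,
                                      **self._tree_kwargs())
            tree.fit(Xf.iloc[boot], y[boot], sample_weight=w[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        self.feature_names_in_ = list(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        return self

    def predict_fraction(self, X):
        if not self.trees_:
            raise ValueError("empty ensemble")
        preds = np.stack([tr.predict_fraction(X) for tr in self.trees_])
        if self.vote:
            return (preds >= 0.5).mean(axis=0)
        return preds.mean(axis=0)

    def predict(self, X):
        return (self.predict_fraction(X) >= 0.5).astype(int)


def _accumulate_importance(node, imp):
    if node.is_leaf:
        return
    imp[node.split.feature] += node.improvement
    _accumulate_importance(node.left, imp)
    _accumulate_importance(node.right, imp)


def fit_bagging(cohort, params: EnsembleParams) -> SurvivalEnsemble:
    """Bagging over survival trees on a Cohort."""
    bp = params.base_params
    est = SurvivalEnsemble(n_trees=params.n_trees, mtry=None, bootstrap=params.bootstrap,
                           random_state=params.seed, cp=bp.cp, maxdepth=bp.maxdepth,
                           minsplit=bp.minsplit, minbucket=bp.minbucket)
    return est.fit(cohort.data, time=cohort.time, event=cohort.event)


def fit_random_forest(cohort, params: EnsembleParams) -> SurvivalEnsemble:
    """Random survival forest: node-level covariate subsampling of size mtry."""
    if params.mtry is None:
        raise ValueError("random forest requires mtry")
    bp = params.base_params
    est = SurvivalEnsemble(n_trees=params.n_trees, mtry=params.mtry,
                           bootstrap=params.bootstrap, random_state=params.seed,
                           cp=bp.cp, maxdepth=bp.maxdepth,
                           minsplit=bp.minsplit, minbucket=bp.minbucket)
    return est.fit(cohort.data, time=cohort.time, event=cohort.event)


def predict_ensemble(ensemble, row):
    """Risk score of one covariate record: geometric-mean HR for survival
    ensembles, mean leaf fraction for classification ensembles."""
    import pandas as pd

    if isinstance(row, dict):
        row = pd.DataFrame([row])
    elif isinstance(row, pd.Series):
        row = row.to_frame().T
    if isinstance(ensemble, SurvivalEnsemble):
        return float(ensemble.predict(row)[0])
    return float(ensemble.predict_fraction(row)[0])
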