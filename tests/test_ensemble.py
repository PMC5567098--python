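"""Bagging / random-forest ensembles: determinism, seed isolation,
out-of-bag behaviour and the log-scale aggregation rule."""

import numpy as np
import pytest

from graftree.cohort import CovariateSpec, HazardModelSpec, generate_cohort
from graftree.ensemble import (
    ClassificationEnsemble,
    EnsembleParams,
    SurvivalEnsemble,
    fit_bagging,
    fit_random_forest,
    predict_ensemble,
)
from graftree.tree import SurvivalTree, TreeParams, tree_to_dict


@pytest.fixture(scope="module")
def interaction_cohort():
    """Two binary covariates whose product drives the hazard."""
    covs = [CovariateSpec(name="a", kind="binary", p=0.5),
            CovariateSpec(name="b", kind="binary", p=0.5),
            CovariateSpec(name="noise", kind="continuous", mean=0, sd=1)]
    hz = HazardModelSpec(baseline_rate=0.002, admin_censor_time=200.0,
                         admin_censor_min=30.0, dropout_rate=0.002)
    c = generate_cohort(800, covs, hz, seed=0)
    # inject the interaction directly: high hazard only when a == b == 1
    rng = np.random.default_rng(1)
    both = (c.data["a"] * c.data["b"]).to_numpy() == 1
    new_event_time = rng.exponential(1 / (0.002 * np.where(both, 5.0, 1.0)))
    censor = rng.uniform(30.0, 200.0, c.n)
    c.time = np.minimum(new_event_time, censor)
    c.event = (new_event_time <= censor).astype(int)
    c.time = np.maximum(c.time, 1e-9)
    return c


def small_params(**kw):
    return EnsembleParams(base_params=TreeParams(maxdepth=3, minsplit=10, minbucket=4), **kw)


class TestBagging:
    def test_single_tree_no_bootstrap_equals_grow_tree(self, interaction_cohort):
        c = interaction_cohort
        ens = fit_bagging(c, small_params(n_trees=1, bootstrap=False))
        single = SurvivalTree(maxdepth=3, minsplit=10, minbucket=4).fit(
            c.data, time=c.time, event=c.event)
        ps = single.predict(c.data)
        pe = ens.predict(c.data)
        # identical wherever the leaf HR is positive; event-free leaves are
        # replaced by their (near-zero) shrunken HR for the log aggregation
        np.testing.assert_allclose(pe[ps > 0], ps[ps > 0])
        assert np.all(pe[ps == 0] < 0.2)

    def test_fixed_seed_reproducible(self, interaction_cohort):
        a = fit_bagging(interaction_cohort, small_params(n_trees=5, seed=3))
        b = fit_bagging(interaction_cohort, small_params(n_trees=5, seed=3))
        for ta, tb in zip(a.trees_, b.trees_):
            assert tree_to_dict(ta)["root"] == tree_to_dict(tb)["root"]

    def test_growing_more_trees_preserves_prefix(self, interaction_cohort):
        a = fit_bagging(interaction_cohort, small_params(n_trees=4, seed=5))
        b = fit_bagging(interaction_cohort, small_params(n_trees=6, seed=5))
        for ta, tb in zip(a.trees_, b.trees_[:4]):
            assert tree_to_dict(ta)["root"] == tree_to_dict(tb)["root"]

    def test_oob_fraction_near_inverse_e(self):
        covs = [CovariateSpec(name="x", kind="continuous", mean=0, sd=1)]
        c = generate_cohort(1000, covs, HazardModelSpec(baseline_rate=0.01), seed=2)
        ens = fit_bagging(c, small_params(n_trees=100, seed=1))
        frac = np.mean([len(oob) / 1000 for oob in ens.oob_indices_])
        assert abs(frac - np.exp(-1)) < 0.03

    def test_bagging_beats_single_tree_oob(self, interaction_cohort):
        """Variance reduction: 50-tree bagging's OOB concordance is at least
        the depth-matched single tree's (median over 10 seeds)."""
        from graftree.metrics import SplitPlan, concordance_index, make_partitions

        c = interaction_cohort
        diffs = []
        for seed in range(10):
            parts = make_partitions(c, SplitPlan(seed=seed))
            Xtr, ttr, etr = (c.data.iloc[parts.train], c.time[parts.train],
                             c.event[parts.train])
            Xte, tte, ete = c.data.iloc[parts.test], c.time[parts.test], c.event[parts.test]
            ens = SurvivalEnsemble(n_trees=50, random_state=seed, maxdepth=8,
                                   minsplit=6, minbucket=3).fit(Xtr, time=ttr, event=etr)
            single = SurvivalTree(maxdepth=8, minsplit=6, minbucket=3).fit(
                Xtr, time=ttr, event=etr)
            c_ens = concordance_index(tte, ete, ens.predict(Xte))
            c_single = concordance_index(tte, ete, single.predict(Xte))
            diffs.append(c_ens - c_single)
        assert np.median(diffs) >= 0

    def test_n_trees_zero_rejected(self, interaction_cohort):
        with pytest.raises(ValueError):
            EnsembleParams(n_trees=0)


class TestRandomForest:
    def test_mtry_total_equals_bagging(self, interaction_cohort):
        c = interaction_cohort
        bag = fit_bagging(c, small_params(n_trees=3, seed=4))
        rf = fit_random_forest(c, small_params(n_trees=3, seed=4, mtry=3))
        for ta, tb in zip(bag.trees_, rf.trees_):
            assert tree_to_dict(ta)["root"] == tree_to_dict(tb)["root"]

    def test_mtry_one_forces_sampled_feature(self, interaction_cohort):
        rf = fit_random_forest(interaction_cohort, small_params(n_trees=5, seed=6, mtry=1))
        # every internal node split one of the three covariates; trees differ
        feats = {tree_to_dict(t)["root"].get("split", {}) and
                 tree_to_dict(t)["root"]["split"]["feature"] for t in rf.trees_}
        assert len(feats) >= 2

    def test_mtry_exceeding_covariates_rejected(self, interaction_cohort):
        with pytest.raises(ValueError, match="mtry"):
            fit_random_forest(interaction_cohort, small_params(n_trees=2, mtry=7))

    def test_importance_ranks_causal_covariate_first(self):
        covs = [CovariateSpec(name="signal", kind="binary", p=0.4),
                CovariateSpec(name="n1", kind="continuous", mean=0, sd=1),
                CovariateSpec(name="n2", kind="continuous", mean=0, sd=1)]
        hz = HazardModelSpec(baseline_rate=0.003, log_hr_effects={"signal": np.log(4)},
                             admin_censor_time=200.0, admin_censor_min=30.0)
        hits = 0
        for seed in range(10):
            c = generate_cohort(600, covs, hz, seed=seed)
            rf = fit_random_forest(c, small_params(n_trees=20, seed=seed, mtry=2))
            hits += int(np.argmax(rf.feature_importances_) == 0)
        assert hits >= 9


class TestAggregation:
    def test_all_root_trees_predict_one(self):
        covs = [CovariateSpec(name="x", kind="continuous", mean=0, sd=1)]
        c = generate_cohort(100, covs, HazardModelSpec(baseline_rate=0.01), seed=3)
        ens = SurvivalEnsemble(n_trees=5, maxdepth=1).fit(c.data, time=c.time,
                                                          event=c.event)
        np.testing.assert_allclose(ens.predict(c.data), 1.0)

    def test_geometric_mean_of_hrs(self):
        ens = SurvivalEnsemble(n_trees=2)
        ens.trees_ = [_ConstantTree(2.0), _ConstantTree(8.0)]
        assert predict_ensemble(ens, {"x": 0.0}) == pytest.approx(4.0)

    def test_prediction_invariant_to_tree_order(self, interaction_cohort):
        c = interaction_cohort
        ens = fit_bagging(c, small_params(n_trees=7, seed=8))
        before = ens.predict(c.data.iloc[:20])
        ens.trees_ = ens.trees_[::-1]
        np.testing.assert_allclose(ens.predict(c.data.iloc[:20]), before)

    def test_classification_ensemble_mean_and_vote(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=300)})
        y = (X["a"] + 0.5 * rng.normal(size=300) > 0).astype(int)
        mean_ens = ClassificationEnsemble(n_trees=10, random_state=1, maxdepth=3,
                                          minsplit=10, minbucket=4).fit(X, y)
        frac = mean_ens.predict_fraction(X)
        assert 0 <= frac.min() and frac.max() <= 1
        mean_ens.vote = True
        votes = mean_ens.predict_fraction(X)
        assert set(np.round(votes * 10)).issubset(set(range(11)))


class _ConstantTree:
    def __init__(self, hr):
        self._hr = hr

    def predict(self, X):
        return np.full(len(X), self._hr)
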