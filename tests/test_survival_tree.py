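"""Survival tree: node statistics, split search vs exhaustive enumeration,
growth, pruning and hazard-ratio prediction."""

import numpy as np
import pandas as pd
import pytest
from _oracles import best_poisson_split, poisson_dev_sum

from conftest import NO_CENSOR, node_frame, random_node, simple_covs
from graftree.cohort import CovariateSpec, HazardModelSpec, generate_cohort
from graftree.tree import (
    SurvivalTree,
    TreeParams,
    best_split,
    grow_tree,
    node_stats,
    predict_hr,
    prune_tree,
)


class TestNodeStats:
    @pytest.mark.parametrize(
        "events, times, rate, dev",
        [
            ([0, 0, 0], [1, 2, 3], 0.0, 0.0),  # no events: every term vanishes
            ([1, 0, 1, 0], [2, 4, 1, 3], 0.2, 0.631432),  # hand-evaluated
            ([1], [5], 0.2, 0.0),  # single observation saturates the rate
        ],
    )
    def test_worked_examples(self, events, times, rate, dev):
        r, d = node_stats(events, times)
        assert r == pytest.approx(rate, abs=1e-12)
        assert d == pytest.approx(dev, abs=1e-6)

    def test_matches_definition_on_random_nodes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, _, events, times = random_node(rng)
            _, d = node_stats(events, times)
            assert d == pytest.approx(poisson_dev_sum(events, times) / len(events), rel=1e-10)
            assert d >= 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            node_stats([], [])
        with pytest.raises(ValueError):
            node_stats([1, 0], [1.0, 0.0])


class TestBestSplit:
    def test_clean_binary_separation(self):
        # one binary covariate separating all events from all non-events
        df = pd.DataFrame({"flag": [1, 1, 1, 0, 0, 0], "noise": [1, 2, 3, 4, 5, 6]})
        c = node_frame([df["flag"].to_numpy(float), df["noise"].to_numpy(float)],
                       ["ordered", "ordered"],
                       np.array([1, 1, 1, 0, 0, 0]), np.ones(6))
        split = best_split(c, TreeParams(minsplit=2, minbucket=1))
        assert split.feature == 0
        assert split.threshold == pytest.approx(0.5)

    def test_constant_covariates_give_none(self):
        c = node_frame([np.ones(10)], ["ordered"],
                       np.array([1, 0] * 5), np.ones(10))
        assert best_split(c, TreeParams(minsplit=2, minbucket=1)) is None

    def test_matches_exhaustive_oracle(self):
        """Vectorised scan equals subset/cut enumeration on random nodes."""
        rng = np.random.default_rng(2024)
        params = TreeParams(minsplit=2, minbucket=1)
        n_with_split = 0
        for _ in range(120):
            columns, kinds, events, times = random_node(rng)
            c = node_frame(columns, kinds, events, times)
            split = best_split(c, params)
            gain, argmax = best_poisson_split(columns, kinds, events, times, 1)
            if split is None:
                assert gain <= 1e-8
                continue
            n_with_split += 1
            assert split.gain == pytest.approx(gain, rel=1e-9, abs=1e-9)
            desc = split.left_categories if split.is_categorical else split.threshold
            keys = {(j, d) for j, d in argmax}
            matched = any(
                j == split.feature
                and (d == desc if isinstance(d, frozenset)
                     else d == pytest.approx(desc, abs=1e-12))
                for j, d in keys
            ) or any(  # complementary categorical subset is the same split
                j == split.feature and isinstance(d, frozenset) and isinstance(desc, frozenset)
                and d == set(np.unique(columns[j])) - desc
                for j, d in keys
            )
            assert matched
        assert n_with_split > 60  # the property is exercised, not vacuous


class TestGrowTree:
    def test_maxdepth_one_is_root_only(self, null_cohort):
        tree = grow_tree(null_cohort, TreeParams(maxdepth=1))
        assert tree.root_.is_leaf
        assert tree.root_.hr == 1.0
        assert np.all(tree.predict(null_cohort.data) == 1.0)

    def test_recovers_binary_effect(self):
        covs = [CovariateSpec(name="flag", kind="binary", p=0.4)]
        hz = HazardModelSpec(baseline_rate=0.002, log_hr_effects={"flag": np.log(4.0)},
                             admin_censor_time=250.0, admin_censor_min=50.0)
        c = generate_cohort(3000, covs, hz, seed=11)
        tree = grow_tree(c, TreeParams(maxdepth=2, minsplit=20, minbucket=7))
        assert not tree.root_.is_leaf
        assert tree.feature_names_in_[tree.root_.split.feature] == "flag"
        hi = tree.root_.left if tree.root_.left.rate > tree.root_.right.rate else tree.root_.right
        lo = tree.root_.left if hi is tree.root_.right else tree.root_.right
        assert 3.2 <= hi.rate / lo.rate <= 4.8

    def test_conservation_and_monotone_improvement(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=4))

        def walk(node):
            if node.is_leaf:
                return
            assert node.left.n + node.right.n == node.n
            assert node.event_sum == pytest.approx(
                node.left.event_sum + node.right.event_sum, abs=1e-9)
            assert node.time_sum == pytest.approx(
                node.left.time_sum + node.right.time_sum, rel=1e-9)
            assert node.improvement > 0
            walk(node.left)
            walk(node.right)

        walk(tree.root_)

    def test_weight_scale_invariance(self, signal_cohort):
        from graftree.tree import tree_to_dict

        t1 = grow_tree(signal_cohort, TreeParams(maxdepth=3),
                       weights=np.ones(signal_cohort.n))
        t2 = grow_tree(signal_cohort, TreeParams(maxdepth=3),
                       weights=2.0 * np.ones(signal_cohort.n))
        d1, d2 = tree_to_dict(t1)["root"], tree_to_dict(t2)["root"]

        def strip(d):
            out = {k: v for k, v in d.items()
                   if k in ("split", "n") or isinstance(v, dict)}
            if d["split"]:
                out["split"] = (d["split"]["feature"], d["split"]["threshold"],
                                tuple(d["split"]["left_categories"] or ()))
            for side in ("left", "right"):
                if side in d:
                    out[side] = strip(d[side])
            return out

        assert strip(d1) == strip(d2)

    def test_all_censored_warns_root_only(self):
        c = node_frame([np.arange(20, dtype=float)], ["ordered"],
                       np.zeros(20, dtype=int), np.ones(20) * 5)
        with pytest.warns(UserWarning, match="zero events"):
            tree = grow_tree(c, TreeParams(maxdepth=3, minsplit=4, minbucket=2))
        assert tree.root_.is_leaf
        assert tree.root_.rate == 0.0
        assert tree.warnings_

    def test_depth2_equals_bruteforce_tree(self):
        """Greedy growth agrees with exhaustive recursion on small nodes."""
        rng = np.random.default_rng(5)
        params = TreeParams(maxdepth=2, minsplit=4, minbucket=2)
        checked = 0
        for _ in range(40):
            columns, kinds, events, times = random_node(rng, n_max=24)
            if events.sum() == 0:
                continue
            c = node_frame(columns, kinds, events, times)
            tree = grow_tree(c, params)

            def brute(cols, kds, ev, tm, depth):
                if depth >= 2 or len(ev) < 4 or ev.sum() == 0:
                    return None
                gain, argmax = best_poisson_split(cols, kds, ev, tm, 2)
                return gain if argmax else None

            root_gain = brute(columns, kinds, events, times, 0)
            if tree.root_.is_leaf:
                assert root_gain is None or root_gain <= 1e-8
            else:
                checked += 1
                assert tree.root_.improvement == pytest.approx(root_gain, rel=1e-9, abs=1e-9)
                for child in (tree.root_.left, tree.root_.right):
                    assert child.is_leaf  # depth bound respected
        assert checked > 10


class TestPrune:
    def test_negative_cp_is_identity(self, signal_cohort):
        from graftree.tree import tree_to_dict

        tree = grow_tree(signal_cohort, TreeParams(maxdepth=4))
        pruned = prune_tree(tree, -1.0)
        assert tree_to_dict(pruned)["root"] == tree_to_dict(tree)["root"]

    def test_huge_cp_leaves_root(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=4))
        assert prune_tree(tree, 10.0).root_.is_leaf

    def test_cp_zero_keeps_positive_improvements(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=4))
        pruned = prune_tree(tree, 0.0)

        def walk(node):
            if node.is_leaf:
                return
            assert node.improvement > 0
            walk(node.left)
            walk(node.right)

        walk(pruned.root_)

    def test_prune_is_subtree(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=5))
        pruned = prune_tree(tree, 0.05)
        n_before = sum(1 for _ in tree.root_.leaves())
        n_after = sum(1 for _ in pruned.root_.leaves())
        assert n_after <= n_before


class TestPredict:
    def test_strong_effect_gives_high_hr(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=2))
        hr1 = predict_hr(tree, {"flag": 1, "level": 0.0, "group": "a"})
        hr0 = predict_hr(tree, {"flag": 0, "level": 0.0, "group": "a"})
        assert hr1 > 1.0 > hr0

    def test_identical_rows_identical_predictions(self, signal_cohort):
        tree = grow_tree(signal_cohort, TreeParams(maxdepth=3))
        row = signal_cohort.data.iloc[[10]]
        assert tree.predict(row)[0] == tree.predict(row.copy())[0]

    def test_missing_at_split_routes_majority_and_logs(self, signal_cohort, caplog):
        import logging

        tree = grow_tree(signal_cohort, TreeParams(maxdepth=2))
        row = signal_cohort.data.iloc[[0]].copy()
        feat = tree.feature_names_in_[tree.root_.split.feature]
        row[feat] = np.nan
        with caplog.at_level(logging.WARNING, logger="graftree"):
            val = tree.predict(row)[0]
        assert np.isfinite(val)
        assert any("majority" in r.message for r in caplog.records)

    def test_fit_rejects_missing_covariates(self, signal_cohort):
        X = signal_cohort.data.copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            SurvivalTree().fit(X, time=signal_cohort.time, event=signal_cohort.event)


def test_threshold_recovery_improves_with_n():
    """The learned root threshold converges toward the simulated cutoff."""
    covs = [CovariateSpec(name="age", kind="continuous", mean=45.0, sd=12.0)]
    hz = HazardModelSpec(baseline_rate=0.002, admin_censor_time=250.0,
                         admin_censor_min=50.0,
                         threshold_effects=(("age", 55.0, np.log(4.0)),))
    errors = {}
    for n in (500, 5000):
        errs = []
        for seed in range(12):
            c = generate_cohort(n, covs, hz, seed=seed)
            tree = grow_tree(c, TreeParams(maxdepth=2))
            if tree.root_.is_leaf:
                errs.append(np.inf)
            else:
                errs.append(abs(tree.root_.split.threshold - 55.0))
        errors[n] = np.median(errs)
    assert errors[5000] < errors[500]
    assert errors[5000] < 2.0
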