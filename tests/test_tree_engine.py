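"""Recursive partitioning: cut points, split search, growth, prediction."""

from __future__ import annotations

import numpy as np
import pytest

from dmrpart import (
    CovariateTable,
    FitConfig,
    TaxaCountMatrix,
    best_split,
    enumerate_cutpoints,
    grow_full_tree,
    llr_statistic,
)
from conftest import make_binary_illustration, make_three_group


class TestCutpoints:
    def test_constant_values_give_no_cuts(self):
        assert enumerate_cutpoints([5, 5, 5], min_bucket=1) == []

    def test_midpoints_of_distinct_values(self):
        cuts = [r.cut_point for r in enumerate_cutpoints([1, 2, 4], min_bucket=1)]
        assert cuts == [1.5, 3.0]

    def test_min_bucket_excludes_edge_cuts(self):
        # 8 samples, min_bucket=5: no cut leaves 5 on both sides
        assert enumerate_cutpoints(range(8), min_bucket=5) == []
        # bucket 3: only cuts with >=3 on each side survive
        cuts = [r.cut_point for r in enumerate_cutpoints(range(8), min_bucket=3)]
        assert cuts == [2.5, 3.5, 4.5]

    def test_nan_values_are_ignored(self):
        vals = [1.0, np.nan, 2.0, 4.0, np.nan]
        cuts = [r.cut_point for r in enumerate_cutpoints(vals, min_bucket=1)]
        assert cuts == [1.5, 3.0]

    def test_ties_collapse_to_one_boundary(self):
        cuts = [r.cut_point for r in enumerate_cutpoints([1, 1, 2, 2], min_bucket=1)]
        assert cuts == [1.5]


class TestBestSplit:
    def test_toy_classification_cut(self):
        # values 1,2,3,4 with classes 0,0,1,1: exhaustive Gini evaluation
        # puts the best cut at 2.5 (both children pure)
        cov = CovariateTable(np.array([1.0, 2.0, 3.0, 4.0]), ["v"])
        labels = np.array([0, 0, 1, 1])
        cfg = FitConfig(min_split=2, min_bucket=1)
        rule = best_split(np.arange(4), labels, cov, cfg, "gini", n_classes=2)
        assert rule.covariate_name == "v"
        assert rule.cut_point == pytest.approx(2.5)

    def test_pure_node_yields_none(self):
        cov = CovariateTable(np.arange(6.0), ["v"])
        labels = np.ones(6, dtype=int)
        cfg = FitConfig(min_split=2, min_bucket=1)
        assert best_split(np.arange(6), labels, cov, cfg, "gini", 2) is None

    def test_identical_dm_rows_yield_none(self):
        counts = TaxaCountMatrix(np.tile([4, 6], (8, 1)))
        cov = CovariateTable(np.arange(8.0), ["v"])
        cfg = FitConfig(min_split=2, min_bucket=1)
        assert best_split(np.arange(8), counts, cov, cfg, "dm") is None

    def test_unknown_criterion(self):
        cov = CovariateTable(np.arange(4.0), ["v"])
        with pytest.raises(ValueError):
            best_split(np.arange(4), np.array([0, 1, 0, 1]), cov,
                       FitConfig(min_split=2, min_bucket=1), "entropy")

    @pytest.mark.parametrize("seed", range(10))
    def test_dm_split_matches_brute_force(self, seed):
        """The vectorized |LLR| scan equals exhaustive (covariate, cut)
        evaluation through the public llr_statistic on small instances."""
        rng = np.random.default_rng(seed)
        n, m = 18, 3
        counts = TaxaCountMatrix(
            rng.multinomial(80, rng.dirichlet(np.ones(4)), size=n))
        cov = CovariateTable(rng.normal(size=(n, m)), [f"c{i}" for i in range(m)])
        cfg = FitConfig(min_split=4, min_bucket=2)

        best, best_score = None, 0.0
        for name in cov.covariate_names:
            for rule in enumerate_cutpoints(cov.column(name), cfg.min_bucket, name):
                left = np.nonzero(cov.column(name) <= rule.cut_point)[0]
                right = np.nonzero(cov.column(name) > rule.cut_point)[0]
                s = abs(llr_statistic(counts, counts.subset(left),
                                      counts.subset(right)))
                if s > best_score + 1e-9:   # same tie rule: first wins
                    best, best_score = rule, s
        got = best_split(np.arange(n), counts, cov, cfg, "dm")
        assert got == best

    @pytest.mark.parametrize("seed", range(10))
    def test_gini_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = 25, 3
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        cov = CovariateTable(rng.normal(size=(n, m)), [f"c{i}" for i in range(m)])
        cfg = FitConfig(min_split=4, min_bucket=2)

        def gini_score(rule):
            v = cov.column(rule.covariate_name)
            li, ri = v <= rule.cut_point, v > rule.cut_point
            def wg(mask):
                sub = labels[mask]
                p = np.bincount(sub, minlength=2) / len(sub)
                return len(sub) * (1 - (p ** 2).sum())
            return wg(np.ones(n, bool)) - wg(li) - wg(ri)

        best, best_score = None, 0.0
        for name in cov.covariate_names:
            for rule in enumerate_cutpoints(cov.column(name), cfg.min_bucket, name):
                s = gini_score(rule)
                if s > best_score + 1e-9:
                    best, best_score = rule, s
        got = best_split(np.arange(n), labels, cov, cfg, "gini", n_classes=2)
        assert got == best

    def test_gini_depth_one_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=60)
            labels = (x + rng.normal(scale=0.7, size=60) > 0).astype(int)
            cov = CovariateTable(x, ["x"])
            cfg = FitConfig(min_split=2, min_bucket=1)
            rule = best_split(np.arange(60), labels, cov, cfg, "gini", 2)
            sk = sklearn.DecisionTreeClassifier(max_depth=1).fit(x[:, None], labels)
            # sklearn stores thresholds at float32 precision
            assert rule.cut_point == pytest.approx(sk.tree_.threshold[0], rel=1e-6)


class TestGrow:
    def test_small_node_stays_root(self):
        cov = CovariateTable(np.arange(5.0), ["v"])
        labels = np.array([0, 1, 0, 1, 0])
        tree = grow_full_tree(labels, cov, FitConfig(min_split=10, min_bucket=5))
        assert tree.n_leaves == 1
        assert tree.root.node_id == 1

    def test_empty_data_rejected(self):
        cov = CovariateTable(np.empty((0, 1)), ["v"])
        with pytest.raises(ValueError):
            grow_full_tree(np.empty(0, dtype=int), cov)

    def test_binary_illustration_full_tree_size(self):
        # region-structured binary outcome on 100 points grows a full tree
        # of about 9 terminal nodes (checked as a band over seeds)
        sizes = []
        for seed in range(15):
            rng = np.random.default_rng(300 + seed)
            Z, cov = make_binary_illustration(rng)
            sizes.append(grow_full_tree(Z, cov).n_leaves)
        assert 7 <= np.mean(sizes) <= 12

    def test_three_group_first_splits_separate_clusters(self):
        # covariate means -1/0/1 with SD 0.2: the first two splits should
        # cut near the cluster boundaries -0.5 and +0.5
        rng = np.random.default_rng(11)
        counts, cov, _ = make_three_group(rng, theta=0.08, sd=0.2)
        tree = grow_full_tree(counts, cov)
        assert not tree.root.is_leaf
        cuts = sorted([tree.root.split.cut_point,
                       *(c.split.cut_point for c in (tree.root.left, tree.root.right)
                         if not c.is_leaf)])
        # both boundaries are found within the low-overlap corridors
        assert any(-0.8 < c < -0.2 for c in cuts)
        assert any(0.2 < c < 0.8 for c in cuts)

    def test_children_partition_parent_everywhere(self, three_group_data):
        counts, cov, _ = three_group_data
        tree = grow_full_tree(counts, cov)
        for nd in tree.internal_nodes():
            merged = np.sort(np.concatenate([nd.left.members, nd.right.members]))
            assert np.array_equal(merged, np.sort(nd.members))
        leaf_members = np.concatenate([l.members for l in tree.leaves()])
        assert np.array_equal(np.sort(leaf_members), np.arange(counts.n_samples))

    def test_growth_invariant_to_sample_order(self, rng):
        counts, cov, _ = make_three_group(rng, group_size=20, reads=500, n_taxa=5)
        perm = rng.permutation(counts.n_samples)
        t1 = grow_full_tree(counts, cov)
        t2 = grow_full_tree(counts.subset(perm),
                            CovariateTable(cov.values[perm], ["c1"]))
        rules1 = sorted((nd.split.covariate_name, round(nd.split.cut_point, 9))
                        for nd in t1.internal_nodes())
        rules2 = sorted((nd.split.covariate_name, round(nd.split.cut_point, 9))
                        for nd in t2.internal_nodes())
        assert rules1 == rules2

    def test_missing_covariate_rows_follow_larger_child(self):
        rng = np.random.default_rng(5)
        counts, cov, _ = make_three_group(rng, group_size=20, reads=500, n_taxa=5)
        vals = cov.values.copy()
        vals[::7, 0] = np.nan
        tree = grow_full_tree(counts, CovariateTable(vals, ["c1"]))
        if not tree.root.is_leaf:
            bigger = max(tree.root.left, tree.root.right, key=lambda c: c.n)
            missing_rows = np.nonzero(np.isnan(vals[:, 0]))[0]
            assert set(missing_rows) <= set(bigger.members.tolist())


class TestPredict:
    def test_root_only_tree_routes_everything_to_root(self):
        cov = CovariateTable(np.arange(4.0), ["v"])
        tree = grow_full_tree(np.array([0, 1, 0, 1]), cov,
                              FitConfig(min_split=10, min_bucket=5))
        assert tree.predict_node({"v": 99.0}) == 1

    def test_boundary_value_goes_left(self):
        cov = CovariateTable(np.array([1.0, 2.0, 3.0, 4.0]), ["v"])
        tree = grow_full_tree(np.array([0, 0, 1, 1]), cov,
                              FitConfig(min_split=2, min_bucket=1))
        cut = tree.root.split.cut_point
        assert tree.predict_node({"v": cut}) == tree.root.left.node_id

    def test_training_samples_route_to_their_leaf(self, three_group_data):
        counts, cov, _ = three_group_data
        tree = grow_full_tree(counts, cov)
        membership = {i: l.node_id for l in tree.leaves() for i in l.members}
        for i in range(counts.n_samples):
            row = dict(zip(cov.covariate_names, cov.values[i]))
            assert tree.predict_node(row) == membership[i]

    def test_predict_composition_root_is_pooled(self, small_counts):
        cov = CovariateTable(np.arange(4.0), ["v"])
        tree = grow_full_tree(small_counts, cov,
                              FitConfig(min_split=10, min_bucket=5))
        pooled = small_counts.counts.sum(axis=0) / small_counts.counts.sum()
        pi = tree.predict_composition({"v": 0.0})
        assert pi == pytest.approx(pooled)
        assert pi.sum() == pytest.approx(1.0)

    def test_composition_requires_dm_mode(self):
        cov = CovariateTable(np.arange(4.0), ["v"])
        tree = grow_full_tree(np.array([0, 0, 1, 1]), cov,
                              FitConfig(min_split=2, min_bucket=1))
        with pytest.raises(ValueError):
            tree.predict_composition({"v": 1.0})
        assert tree.predict_class_distribution({"v": 1.0}).sum() == pytest.approx(1.0)

    def test_missing_required_covariate_raises(self):
        cov = CovariateTable(np.array([1.0, 2.0, 3.0, 4.0]), ["v"])
        tree = grow_full_tree(np.array([0, 0, 1, 1]), cov,
                              FitConfig(min_split=2, min_bucket=1))
        with pytest.raises(KeyError):
            tree.predict_node({"other": 1.0})

    def test_held_out_composition_recovers_generating_group(self):
        # routed pi-hat should sit closest (squared Euclidean) to the
        # generating group's pi for >=90% of fresh samples
        rng = np.random.default_rng(77)
        counts, cov, labels = make_three_group(rng, theta=0.08, sd=0.2)
        tree = grow_full_tree(counts, cov)
        from dmrpart import body_site_profiles
        pis = body_site_profiles(10)
        new_counts, new_cov, new_labels = make_three_group(rng, group_size=30,
                                                           theta=0.08, sd=0.2)
        hits = 0
        for i in range(new_cov.n_samples):
            row = dict(zip(new_cov.covariate_names, new_cov.values[i]))
            pred = tree.predict_composition(row)
            d = [((pred - p) ** 2).sum() for p in pis]
            hits += int(np.argmin(d) == new_labels[i])
        assert hits / new_cov.n_samples >= 0.9
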