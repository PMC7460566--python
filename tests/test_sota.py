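import itertools
import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from profilex import (
    SotaHierarchy,
    SotaParams,
    SynthConfig,
    generate,
    grow_levels,
    make_hierarchical_blocks,
    sample_space_score,
    select_per_level,
    sota_two_cell,
)
from naive import naive_corr_dist


def two_block_profiles(rng, n_per_block=5, n_features=8, noise=0.05):
    shape = rng.normal(size=n_features)
    a = shape + noise * rng.normal(size=(n_per_block, n_features))
    b = -shape + noise * rng.normal(size=(n_per_block, n_features))
    return np.vstack([a, b]), np.repeat([0, 1], n_per_block)


class TestTwoCellSplit:
    def test_anticorrelated_groups_split_exactly(self, rng):
        X, truth = two_block_profiles(rng)
        assignment, cells = sota_two_cell(X)
        assert adjusted_rand_score(truth, assignment) == 1.0
        assert cells.shape == (2, X.shape[1])

    def test_two_distinct_profiles_one_per_cell(self):
        X = np.array([[1.0, 2, 3, 4], [4, 3, 2, 1]])
        assignment, _ = sota_two_cell(X)
        assert set(assignment) == {0, 1}

    def test_matches_exhaustive_partition_minimizer(self):
        """On 12 profiles the split equals the best of all 2-partitions."""
        rng = np.random.default_rng(7)
        X, truth = two_block_profiles(rng, n_per_block=6, noise=0.1)
        assignment, _ = sota_two_cell(X)
        assert adjusted_rand_score(truth, assignment) == 1.0

        def within_cost(mask):
            cost = 0.0
            for side in (0, 1):
                members = X[mask == side]
                center = members.mean(axis=0)
                cost += sum(naive_corr_dist(m, center) for m in members)
            return cost

        best_mask, best_cost = None, np.inf
        for bits in itertools.product([0, 1], repeat=11):
            mask = np.array((0,) + bits)
            if mask.min() == mask.max():
                continue
            c = within_cost(mask)
            if c < best_cost:
                best_mask, best_cost = mask, c
        assert adjusted_rand_score(best_mask, assignment) == 1.0

    def test_identical_profiles_degenerate(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            assignment, _ = sota_two_cell(X)
        assert len(set(assignment)) == 1

    def test_recovers_planted_blocks_over_seeds(self):
        """ARI = 1 whenever blocks are anti-correlated and internally tight."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, truth = two_block_profiles(rng, n_per_block=15, noise=0.2)
            assignment, _ = sota_two_cell(X)
            assert adjusted_rand_score(truth, assignment) == 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SotaParams(lr_winner=0.01, lr_mother=0.05, lr_sister=0.1)
        with pytest.raises(ValueError):
            sota_two_cell(np.ones((1, 4)))


class TestGrowLevels:
    def test_four_separable_blocks_at_level_two(self):
        rng = np.random.default_rng(0)
        shapes = np.array(
            [[1.0, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1],
             [1, 3, 1, 3, 1, 3], [3, 1, 3, 1, 3, 1]]
        )
        X = np.vstack([
            s + 0.02 * rng.normal(size=(6, 6)) for s in shapes
        ])
        truth = np.repeat(np.arange(4), 6)
        tree = grow_levels(X, 2)
        assert tree.n_clusters(2) == 4
        assert adjusted_rand_score(truth, tree.levels[2]) == 1.0

    def test_partition_and_nesting_invariants(self, default_synth):
        ds, _, truth = default_synth
        X = ds.values[:, truth.informative_mask].T
        tree = grow_levels(X, 3)
        n = X.shape[0]
        for level in (1, 2, 3):
            assign = tree.levels[level]
            assert assign.shape == (n,)
            assert tree.n_clusters(level) <= 2**level
            sizes = np.bincount(assign)
            assert sizes.sum() == n and (sizes > 0).all()
        # each deeper cluster maps into exactly one parent cluster
        for level in (2, 3):
            child, parent = tree.levels[level], tree.levels[level - 1]
            for k in range(tree.n_clusters(level)):
                assert len(set(parent[child == k])) == 1

    def test_min_split_size_carries_small_leaves(self):
        rng = np.random.default_rng(1)
        X, _ = two_block_profiles(rng, n_per_block=3)
        tree = grow_levels(X, 4, SotaParams(min_split_size=4))
        # leaves below 4 members must pass through unsplit
        final_sizes = np.bincount(tree.levels[4])
        assert (final_sizes >= 1).all()
        assert tree.n_clusters(4) <= 6

    def test_deterministic(self, default_synth):
        ds, _, truth = default_synth
        X = ds.values[:, truth.informative_mask].T
        t1 = grow_levels(X, 2)
        t2 = grow_levels(X, 2)
        np.testing.assert_array_equal(t1.levels[2], t2.levels[2])

    def test_complete_binary_hierarchy_counts(self):
        """Separable hierarchical blocks double the cluster count per level."""
        profiles, _ = make_hierarchical_blocks(depth=5, n_features=32)
        tree = grow_levels(profiles, 5)
        for level in range(1, 6):
            assert tree.n_clusters(level) == 2**level


class TestLevelSelection:
    def test_planted_argmin_cluster_selected(self, default_synth):
        ds, labels, truth = default_synth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = grow_levels(ds.values.T, 1)
            sel = select_per_level(tree, ds, labels, size_bounds=(3, np.inf))
            chosen = sel.best_cluster(1)
            members = tree.members(1, chosen)
            # brute-force check: the chosen cluster scores minimal
            scores = {}
            for k in range(tree.n_clusters(1)):
                idx = tree.members(1, k)
                if idx.size >= 3:
                    scores[k] = sample_space_score(ds, labels, idx).qc_int
        assert chosen == min(scores, key=scores.get)
        roles = np.array(truth.gene_roles)[members]
        assert np.char.startswith(roles, "block").mean() > 0.5

    def test_selection_deterministic(self, default_synth):
        ds, labels, truth = default_synth
        X = ds.values[:, truth.informative_mask]
        from profilex import ExpressionDataset

        sub = ExpressionDataset(X, ds.sample_ids,
                                [g for g, m in zip(ds.gene_ids, truth.informative_mask) if m])
        tree = grow_levels(sub.values.T, 2)
        s1 = select_per_level(tree, sub, labels, (3, np.inf))
        s2 = select_per_level(tree, sub, labels, (3, np.inf))
        assert s1.cluster_ids == s2.cluster_ids
        assert s1.scores == s2.scores

    def test_unselectable_level_marked(self, tiny_dataset, tiny_labels):
        tree = grow_levels(tiny_dataset.values.T, 1)
        sel = select_per_level(tree, tiny_dataset, tiny_labels,
                               size_bounds=(100, np.inf))
        assert sel.cluster_ids == [None]


class TestEstimatorInterface:
    def test_fit_exposes_levels(self, default_synth):
        ds, _, truth = default_synth
        est = SotaHierarchy(max_level=2)
        est.fit(ds.values[:, truth.informative_mask].T)
        assert est.labels_.shape == (int(truth.informative_mask.sum()),)
        assert est.level_labels(1).max() <= 1

    def test_training_error_decreases(self):
        """Total winner distance shrinks monotonically up to tolerance."""
        rng = np.random.default_rng(5)
        X, _ = two_block_profiles(rng, n_per_block=10, noise=0.3)
        from profilex.sota import _corr_dist_to_cells, _normalise_rows

        params = SotaParams()
        centroid = X.mean(axis=0)
        eps = 1e-6 * np.where(np.arange(X.shape[1]) % 2 == 0, 1.0, -1.0)
        cells = np.vstack([centroid + eps, centroid - eps])
        X_hat = _normalise_rows(X)
        errors = []
        for _ in range(15):
            err = 0.0
            for i in range(X.shape[0]):
                d = _corr_dist_to_cells(X_hat[i], cells)
                w = int(np.argmin(d))
                err += d[w]
                cells[w] += params.lr_winner * (X[i] - cells[w])
                cells[1 - w] += params.lr_sister * (X[i] - cells[1 - w])
            errors.append(err)
        diffs = np.diff(errors)
        assert np.all(diffs <= 1e-6 + 0.05 * np.abs(np.array(errors[:-1])))
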