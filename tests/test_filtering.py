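import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profilex import (
    EntropyBoundaryFilter,
    ExpressionDataset,
    SampleLabels,
    SynthConfig,
    apply_boundaries,
    build_grid,
    gene_statistics,
    generate,
    qc_int,
    scan_boundaries,
    shannon_entropy_js,
)
from profilex.filtering import GeneStats
from profilex.quality import Partition
from naive import naive_qc_int


def make_dataset(values):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        values,
        [f"s{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
    )


class TestGeneStatistics:
    def test_constant_gene(self):
        ds = make_dataset(np.column_stack([np.full(4, 3.0), np.arange(4.0)]))
        stats = gene_statistics(ds)
        assert stats.variance[0] == 0.0
        assert stats.mean_abs[0] == 3.0
        assert stats.entropy[0] == 0.0

    def test_alternating_profile_hand_values(self):
        ds = make_dataset(np.column_stack([[1.0, -1, 1, -1], np.arange(4.0)]))
        stats = gene_statistics(ds)
        assert stats.mean_abs[0] == pytest.approx(1.0)
        assert stats.variance[0] == pytest.approx(4.0 / 3.0)  # n-1 denominator

    def test_scaling_behaviour(self, rng):
        base = rng.normal(size=(10, 3))
        s1 = gene_statistics(make_dataset(base))
        s2 = gene_statistics(make_dataset(2.0 * base))
        np.testing.assert_allclose(s2.variance, 4.0 * s1.variance, rtol=1e-12)
        np.testing.assert_allclose(s2.mean_abs, 2.0 * s1.mean_abs, rtol=1e-12)
        # equal-width bins over the scaled range keep the same occupancy
        np.testing.assert_allclose(s2.entropy, s1.entropy, rtol=1e-12)


class TestShrinkageEntropy:
    def test_constant_profile_zero(self):
        assert shannon_entropy_js(np.full(6, 2.5)) == 0.0

    def test_uniform_occupancy_is_ln_b(self):
        # values landing exactly one per bin in every bin
        profile = np.linspace(0, 1, 10) + 0.05
        profile[0], profile[-1] = 0.0, 1.0
        h = shannon_entropy_js(profile, n_bins=10)
        assert h == pytest.approx(np.log(10), abs=1e-12)

    def test_hand_evaluated_shrinkage_case(self):
        # 4 values, bins (3,1): lambda = 0.375/0.375 = 1 -> uniform -> ln 2
        h = shannon_entropy_js(np.array([0.0, 0.1, 0.2, 1.0]), n_bins=2)
        assert h == pytest.approx(np.log(2), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            h = shannon_entropy_js(rng.normal(size=30), n_bins=8)
            assert 0.0 <= h <= np.log(8) + 1e-12

    def test_too_short_profile(self):
        with pytest.raises(ValueError):
            shannon_entropy_js(np.array([1.0]))


class TestBoundaryGrid:
    def test_single_step_at_loosest_bounds(self):
        stats = GeneStats(np.array([0.5, 2.0]), np.array([1.0, 3.0]),
                          np.array([0.2, 1.4]))
        grid = build_grid(stats, 1)
        assert (grid.v_grid[0], grid.m_grid[0], grid.h_grid[0]) == (0.5, 1.0, 1.4)

    def test_three_step_linear_spacing(self):
        stats = GeneStats(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                          np.array([0.0, 1.0]))
        grid = build_grid(stats, 3)
        np.testing.assert_allclose(grid.v_grid, [0, 0.5, 1])
        np.testing.assert_allclose(grid.m_grid, [0, 0.5, 1])
        np.testing.assert_allclose(grid.h_grid, [1, 0.5, 0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=20),
        st.integers(2, 40),
    )
    def test_grids_monotone_with_observed_extremes(self, var, n_steps):
        v = np.array(var)
        stats = GeneStats(v, v + 1.0, np.log1p(v))
        grid = build_grid(stats, n_steps)
        assert grid.v_grid[0] == v.min() and grid.v_grid[-1] == v.max()
        assert grid.h_grid[0] == stats.entropy.max()
        assert grid.h_grid[-1] == stats.entropy.min()
        assert np.all(np.diff(grid.v_grid) >= 0)
        assert np.all(np.diff(grid.h_grid) <= 0)


class TestApplyBoundaries:
    def setup_method(self):
        self.stats = GeneStats(
            variance=np.array([0.0, 0.0, 1.0, 2.0, 3.0]),
            mean_abs=np.array([1.0, 1.0, 1.0, 1.0, 1.0]),
            entropy=np.array([0.5, 0.5, 0.5, 0.5, 0.5]),
        )

    def test_permissive_bounds_keep_all(self):
        mask = apply_boundaries(self.stats, -1.0, -1.0, 10.0)
        assert mask.all()

    def test_tightest_bounds_drop_all(self):
        mask = apply_boundaries(self.stats, 3.0, 1.0, 0.5)
        assert not mask.any()

    def test_planted_zero_variance_removed(self):
        mask = apply_boundaries(self.stats, 0.5, -1.0, 10.0)
        np.testing.assert_array_equal(mask, [False, False, True, True, True])

    def test_all_fail_removed_mode_keeps_partial_passers(self):
        # gene 0 fails variance only -> kept in the remove-if-all-fail reading
        mask = apply_boundaries(self.stats, 0.5, -1.0, 10.0,
                                mode="all_fail_removed")
        assert mask.all()


class TestScanBoundaries:
    def test_single_step_equals_full_data_criterion(self, tiny_dataset, tiny_labels):
        stats = gene_statistics(tiny_dataset)
        grid = build_grid(stats, 1)
        res = scan_boundaries(tiny_dataset, tiny_labels, grid)
        assert res.qc_per_step.shape == (1,)
        full = qc_int(tiny_dataset.values, Partition([0, 1, 0, 1])).qc_int
        assert res.qc_per_step[0] == pytest.approx(full, abs=1e-12)
        assert res.kept_mask.all()

    def test_noise_removed_informative_retained(self):
        """20 informative + 20 chaotic genes: the QC minimum drops the noise.

        The surviving set may be a high-variance subset of the block genes
        (the criterion keeps tightening while the kept genes sharpen class
        separation), but it must stay overwhelmingly informative.
        """
        cfg = SynthConfig(n_blocks=2, genes_per_block=10, n_noise_genes=20,
                          n_low_genes=20, seed=1)
        ds, labels, truth = generate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_boundaries(ds, labels, build_grid(gene_statistics(ds)))
        roles = np.array(truth.gene_roles)
        assert (~res.kept_mask)[roles == "noise"].sum() >= 18
        assert (~res.kept_mask)[roles == "low"].all()
        kept_roles = roles[res.kept_mask]
        assert np.char.startswith(kept_roles, "block").mean() >= 0.8
        assert res.kept_mask[truth.informative_mask].sum() >= 5

    def test_kept_counts_non_increasing(self, default_synth):
        ds, labels, _ = default_synth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_boundaries(ds, labels, build_grid(gene_statistics(ds)))
        assert np.all(np.diff(res.genes_per_step) <= 0)
        assert res.best_step == int(np.argmin(res.qc_per_step))
        assert res.genes_per_step[res.best_step] == res.kept_mask.sum()

    def test_qc_values_match_naive_reimplementation(self, tiny_dataset, tiny_labels):
        stats = gene_statistics(tiny_dataset)
        grid = build_grid(stats, 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_boundaries(tiny_dataset, tiny_labels, grid)
        for s in range(6):
            if not np.isfinite(res.qc_per_step[s]):
                continue
            mask = (
                np.ones(tiny_dataset.n_genes, dtype=bool) if s == 0
                else apply_boundaries(stats, grid.v_grid[s], grid.m_grid[s],
                                      grid.h_grid[s])
            )
            want = naive_qc_int(tiny_dataset.values[:, mask].tolist(), [0, 1, 0, 1])
            assert res.qc_per_step[s] == pytest.approx(want, abs=1e-10)

    def test_gene_permutation_equivariance(self, rng):
        cfg = SynthConfig(n_blocks=2, genes_per_block=8, n_noise_genes=10,
                          n_low_genes=5, seed=3)
        ds, labels, _ = generate(cfg)
        perm = rng.permutation(ds.n_genes)
        permuted = ExpressionDataset(
            ds.values[:, perm], ds.sample_ids,
            [ds.gene_ids[j] for j in perm],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_a = scan_boundaries(ds, labels, build_grid(gene_statistics(ds)))
            res_b = scan_boundaries(permuted, labels,
                                    build_grid(gene_statistics(permuted)))
        np.testing.assert_allclose(res_a.qc_per_step, res_b.qc_per_step,
                                   atol=1e-10)
        np.testing.assert_array_equal(res_a.kept_mask[perm], res_b.kept_mask)


class TestEstimatorInterface:
    def test_fit_transform_selects_genes(self, default_synth):
        ds, labels, truth = default_synth
        y = labels.vector(ds.sample_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = EntropyBoundaryFilter().fit(ds.values, y)
        reduced = sel.transform(ds.values)
        assert reduced.shape == (ds.n_samples, sel.support_mask_.sum())
        assert sel.get_support().dtype == bool
        # chaotic and weakly-expressed genes are overwhelmingly dropped
        uninformative = ~truth.informative_mask
        assert (~sel.support_mask_)[uninformative].mean() >= 0.9

    def test_params_round_trip(self):
        sel = EntropyBoundaryFilter(n_steps=7, n_bins=5, mode="all_fail_removed")
        assert EntropyBoundaryFilter(**sel.get_params()).get_params() == sel.get_params()
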