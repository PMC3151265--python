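import numpy as np
import pytest
from scipy import stats

import phylopart as pp
from phylopart.likelihood import FittedModel, ModelSpec, optimize_fit
from phylopart.models import NucleotideModel, discretize_gamma
from phylopart.selection import (ModelComparisonRow, aicc_partitioned,
                                 bic_partitioned, build_comparison_table,
                                 congruence_summary,
                                 hierarchical_gene_model_test,
                                 likelihood_ratio_test,
                                 nonparametric_bootstrap,
                                 parameter_heterogeneity_summary,
                                 rell_bootstrap)
from phylopart.simulate import simulate_alignment


class TestLRT:
    def test_equal_likelihoods(self):
        stat, p = likelihood_ratio_test(-100.0, -100.0, df=1)
        assert stat == 0.0
        assert p == 1.0

    def test_critical_value_df1(self):
        stat, p = likelihood_ratio_test(-100.0, -100.0 + 3.841 / 2, df=1)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_matches_chi2_oracle(self):
        for df in (1, 4, 8):
            stat, p = likelihood_ratio_test(-50.0, -42.0, df=df)
            assert stat == pytest.approx(16.0)
            assert p == pytest.approx(stats.chi2.sf(16.0, df))

    def test_broken_nesting_signalled(self):
        with pytest.raises(ValueError, match="nest"):
            likelihood_ratio_test(-100.0, -100.5, df=2)

    def test_tiny_negative_clipped(self):
        stat, p = likelihood_ratio_test(-100.0, -100.0 - 1e-8, df=1)
        assert stat == 0.0 and p == 1.0

    def test_df_validated(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-10.0, -9.0, df=0)


class TestAICcBIC:
    def test_aicc_single_partition_example(self):
        # -2*(-500) + 2*2 + 2*2*3/(100-3) = 1000 + 4 + 12/97
        val = aicc_partitioned(-500.0, [2], [100])
        assert val == pytest.approx(1000 + 4 + 12 / 97)
        assert val == pytest.approx(1004.1237, abs=1e-4)

    def test_aicc_zero_params(self):
        assert aicc_partitioned(-500.0, [0, 0], [50, 50]) == 1000.0

    def test_aicc_additive_over_partitions(self):
        both = aicc_partitioned(-500.0, [3, 5], [200, 300])
        a = aicc_partitioned(0.0, [3], [200])
        b = aicc_partitioned(0.0, [5], [300])
        assert both == pytest.approx(1000.0 + a + b)

    def test_aicc_small_sample_breakdown_named(self):
        with pytest.raises(ValueError, match="gene2"):
            aicc_partitioned(-10.0, [2, 10], [100, 11],
                             names=["gene1", "gene2"])

    def test_bic_single_partition_example(self):
        val = bic_partitioned(-500.0, [2], [100])
        assert val == pytest.approx(1000 + 2 * np.log(100))
        assert val == pytest.approx(1009.2103, abs=1e-4)

    def test_bic_zero_params_and_additivity(self):
        assert bic_partitioned(-500.0, [0], [100]) == 1000.0
        both = bic_partitioned(-500.0, [3, 5], [200, 300])
        assert both == pytest.approx(
            1000.0 + 3 * np.log(200) + 5 * np.log(300))

    def test_bic_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            bic_partitioned(-10.0, [1], [0])


class TestRellBootstrap:
    def test_single_tree_full_support(self):
        M = np.full((1, 50), -1.0)
        res = rell_bootstrap(M, n_samples=100, seed=0)
        assert res.tree_support[0] == 1.0

    def test_dominant_tree(self):
        rng = np.random.default_rng(1)
        M = np.vstack([np.full(100, -1.0), np.full(100, -1.5)])
        res = rell_bootstrap(M, n_samples=200, seed=1)
        assert res.tree_support[0] == 1.0
        assert res.tree_support[1] == 0.0

    def test_supports_sum_to_one(self):
        rng = np.random.default_rng(2)
        M = rng.normal(-2, 0.5, size=(5, 300))
        res = rell_bootstrap(M, n_samples=500, seed=3)
        assert res.tree_support.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tie_splitting(self):
        M = np.zeros((3, 10))
        res = rell_bootstrap(M, n_samples=100, seed=4)
        assert np.allclose(res.tree_support, 1 / 3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(4, 100))
        a = rell_bootstrap(M, n_samples=200, seed=9).tree_support
        b = rell_bootstrap(M, n_samples=200, seed=9).tree_support
        assert np.array_equal(a, b)

    def test_stratified_option(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(3, 60))
        strata = [np.arange(0, 30), np.arange(30, 60)]
        res = rell_bootstrap(M, n_samples=100, seed=7, strata=strata)
        assert res.tree_support.sum() == pytest.approx(1.0)

    def test_bipartition_support(self):
        t1 = pp.read_newick("((A,B),(C,D));")
        t2 = pp.read_newick("((A,C),(B,D));")
        M = np.vstack([np.full(50, -1.0), np.full(50, -2.0)])
        res = rell_bootstrap(M, n_samples=100, seed=8, trees=[t1, t2])
        ab = frozenset({"C", "D"})  # canonical side (not containing 'A')
        assert res.bipartition_support[ab] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rell_bootstrap(np.empty((0, 5)), n_samples=10, seed=0)


@pytest.fixture(scope="module")
def clean_sim():
    tree = pp.read_newick(
        "((A:0.2,B:0.15):0.08,((C:0.18,D:0.12):0.09,"
        "(E:0.15,F:0.2):0.07):0.08);")
    model = NucleotideModel.hky(np.array([0.3, 0.2, 0.2, 0.3]), 3.0)
    aln = simulate_alignment(tree, model, discretize_gamma(0.7, 6), 2000,
                             seed=33)
    return tree, aln


class TestNonparametricBootstrap:
    def test_clean_signal_full_support(self, clean_sim):
        tree, aln = clean_sim
        support = nonparametric_bootstrap(aln, ModelSpec("HKY"), tree,
                                          n_reps=10, seed=5)
        assert set(support) == tree.bipartitions()
        for v in support.values():
            assert 0.0 <= v <= 1.0
        assert min(support.values()) > 0.9

    def test_determinism(self, clean_sim):
        tree, aln = clean_sim
        a = nonparametric_bootstrap(aln, ModelSpec("JC"), tree, n_reps=3,
                                    seed=11)
        b = nonparametric_bootstrap(aln, ModelSpec("JC"), tree, n_reps=3,
                                    seed=11)
        assert a == b

    def test_n_reps_validated(self, clean_sim):
        tree, aln = clean_sim
        with pytest.raises(ValueError):
            nonparametric_bootstrap(aln, ModelSpec("JC"), tree, n_reps=0)


class TestHierarchicalModelTest:
    def test_rev_data_selects_rev(self, clean_sim):
        tree, _ = clean_sim
        model = NucleotideModel.rev(
            np.array([0.35, 0.15, 0.2, 0.3]),
            np.array([0.2, 6.0, 1.5, 0.3, 10.0, 1.0]))
        aln = simulate_alignment(tree, model, discretize_gamma(0.7, 6),
                                 3000, seed=40)
        res = hierarchical_gene_model_test(aln, tree)
        assert res.best.kind.value == "REV"
        assert res.p_hky_vs_rev < 0.001

    def test_chain_is_monotone(self, clean_sim):
        tree, aln = clean_sim
        res = hierarchical_gene_model_test(aln, tree)
        assert res.fits["HKY"].loglik >= res.fits["JC"].loglik - 1e-6
        assert res.fits["REV"].loglik >= res.fits["HKY"].loglik - 1e-6

    def test_site_order_invariance(self, clean_sim):
        tree, aln = clean_sim
        rng = np.random.default_rng(3)
        perm = rng.permutation(aln.total_length)
        shuffled = aln.subset_sites(perm)
        a = hierarchical_gene_model_test(aln, tree)
        b = hierarchical_gene_model_test(shuffled, tree)
        assert a.best.kind == b.best.kind
        assert a.p_jc_vs_hky == pytest.approx(b.p_jc_vs_hky, abs=1e-5)


class TestCongruence:
    def test_identical_trees(self):
        t = pp.read_newick("((A,B),(C,(D,E)));")
        c = congruence_summary([t, t.copy(), t.copy()], n_sims=50, seed=0)
        assert c.n_distinct == 1
        assert c.mean_pairwise_rf == 0.0
        assert c.p_value == 0.0  # random trees never reach mean RF 0

    def test_two_identical_one_distant(self):
        t1 = pp.read_newick("(((A,B),C),(D,(E,F)));")
        t2 = pp.read_newick("(((A,F),D),(C,(B,E)));")
        assert pp.robinson_foulds_normalized(t1, t2) == 1.0
        c = congruence_summary([t1, t1.copy(), t2], n_sims=20, seed=1)
        assert c.n_distinct == 2
        assert c.mean_pairwise_rf == pytest.approx(2 / 3)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(7)]
        trees = [pp.random_topology(taxa, rng=rng) for _ in range(5)]
        a = congruence_summary(trees, n_sims=30, seed=5)
        b = congruence_summary(trees[::-1], n_sims=30, seed=5)
        assert a.n_distinct == b.n_distinct
        assert a.mean_pairwise_rf == pytest.approx(b.mean_pairwise_rf)

    def test_mismatched_leaves_rejected(self):
        t1 = pp.read_newick("((A,B),(C,D));")
        t2 = pp.read_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            congruence_summary([t1, t2], n_sims=5, seed=0)


class TestHeterogeneitySummary:
    def _fit_for(self, R, alpha):
        kappa = 2 * R  # equal frequencies: R = kappa/2
        m = NucleotideModel.hky(np.full(4, 0.25), kappa)
        t = pp.read_newick("(A:0.1,B:0.1);")
        return FittedModel(t, m, discretize_gamma(alpha, 6), -1.0, 5)

    def test_percentiles_and_ranges(self):
        Rs = np.linspace(1.0, 3.0, 11)
        alphas = np.linspace(0.3, 0.9, 11)
        fits = [self._fit_for(r, a) for r, a in zip(Rs, alphas)]
        alns = [pp.compress_patterns(["A", "B"], ["ACGT", "ACGT"])] * 11
        df, summary = parameter_heterogeneity_summary(fits, alns)
        assert np.allclose(df["R"], Rs, atol=1e-12)
        assert summary["R"]["min"] == pytest.approx(1.0)
        assert summary["R"]["max"] == pytest.approx(3.0)
        assert summary["R"]["p2.5"] == pytest.approx(
            np.percentile(Rs, 2.5))
        assert summary["alpha"]["p97.5"] == pytest.approx(
            np.percentile(alphas, 97.5))

    def test_gc_of_all_gc_alignment(self):
        fits = [self._fit_for(1.5, 0.5)]
        alns = [pp.compress_patterns(["A", "B"], ["GCGC", "CGCG"])]
        df, summary = parameter_heterogeneity_summary(fits, alns)
        assert df["gc"].iloc[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parameter_heterogeneity_summary([], [])


class TestComparisonTable:
    def test_delta_columns(self):
        rows = [
            ModelComparisonRow("REV+G", "concat", "T1", -1000, 42,
                               aicc=2100.0, bic=2200.0),
            ModelComparisonRow("REV+G", "by-gene", "T1", -900, 84,
                               aicc=2050.0, bic=2250.0, lrt_p=1e-9),
        ]
        df = build_comparison_table(rows)
        assert (df["dAICc"] == 0).sum() == 1
        assert df["dAICc"].min() == 0.0
        assert (df["dAICc"] >= 0).all()
        assert df.loc[0, "dAICc"] == pytest.approx(50.0)
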