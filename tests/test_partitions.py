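import numpy as np
import pytest

import phylopart as pp
from phylopart.likelihood import ModelSpec, optimize_fit
from phylopart.models import NucleotideModel, discretize_gamma
from phylopart.partitions import (PartitionMode, PartitionScheme,
                                  SharingPolicy, apply_partition_labels,
                                  count_free_parameters, fit_codon_partitioned,
                                  fit_gene_partitioned, read_raxml_partitions,
                                  read_partition_table, split_codon_positions,
                                  write_partition_table,
                                  write_raxml_partitions)
from phylopart.simulate import simulate_alignment


@pytest.fixture(scope="module")
def codon_sim():
    """6-taxon gene with a strong third-position rate multiplier."""
    tree = pp.read_newick(
        "((A:0.15,B:0.1):0.05,((C:0.12,D:0.09):0.06,"
        "(E:0.11,F:0.14):0.05):0.04);")
    model = NucleotideModel.hky(np.array([0.3, 0.2, 0.2, 0.3]), 2.5)
    gamma = discretize_gamma(0.8, 6)
    aln = simulate_alignment(tree, model, gamma, 6000,
                             position_multipliers=(1.0, 0.5, 3.0), seed=21)
    return tree, aln


class TestSplitCodonPositions:
    def test_length_nine(self):
        aln = pp.compress_patterns(["a", "b"], ["ACGTACGTA", "ACGTACGTA"])
        parts = split_codon_positions(aln)
        assert [p.tolist() for p in parts] == [[0, 3, 6], [1, 4, 7], [2, 5, 8]]

    def test_not_divisible_rejected(self):
        aln = pp.compress_patterns(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        with pytest.raises(ValueError, match="divisible"):
            split_codon_positions(aln)

    def test_uses_labels_when_present(self):
        aln = pp.compress_patterns(
            ["a", "b"], ["ACGTAC", "ACGTAC"],
            codon_positions=np.array([3, 1, 2, 3, 1, 2]))
        parts = split_codon_positions(aln)
        assert parts[0].tolist() == [1, 4]
        assert parts[2].tolist() == [0, 3]


class TestSchemes:
    def test_concatenated_single_partition(self, codon_sim):
        _, aln = codon_sim
        s = PartitionScheme.for_alignment(aln, PartitionMode.CONCATENATED)
        assert s.sizes() == [aln.total_length]

    def test_by_codon_three_equal(self, codon_sim):
        _, aln = codon_sim
        s = PartitionScheme.for_alignment(aln, PartitionMode.BY_CODON_POSITION)
        assert s.sizes() == [2000, 2000, 2000]

    def test_by_gene(self):
        aln = pp.compress_patterns(["a", "b"], ["ACGTAC", "ACGTAC"],
                                   gene_ids=list("xxxyyy"))
        s = PartitionScheme.for_alignment(aln, PartitionMode.BY_GENE)
        assert s.names == ["x", "y"]
        assert s.sizes() == [3, 3]


class TestCodonPartitionedFit:
    def test_shared_policy_equals_concatenated(self, codon_sim):
        tree, aln = codon_sim
        spec = ModelSpec("HKY")
        base = optimize_fit(tree, aln, spec, tol=1e-4)
        shared = fit_codon_partitioned(tree, aln, spec,
                                       SharingPolicy.shared(), tol=1e-4)
        assert shared.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert sum(f.loglik for f in shared.position_fits) == pytest.approx(
            base.loglik, abs=1e-6)

    def test_separate_equals_independent_fits(self, codon_sim):
        tree, aln = codon_sim
        spec = ModelSpec("HKY")
        sep = fit_codon_partitioned(tree, aln, spec,
                                    SharingPolicy.separate(), tol=1e-4)
        indep = sum(
            optimize_fit(tree, aln.subset_sites(idx), spec, tol=1e-4).loglik
            for idx in split_codon_positions(aln))
        assert sep.loglik == pytest.approx(indep, abs=1e-4)

    def test_ladder_is_monotone(self, codon_sim):
        tree, aln = codon_sim
        spec = ModelSpec("HKY")
        lls = []
        for pol in (SharingPolicy.shared(), SharingPolicy.rates(),
                    SharingPolicy.rates_freqs(), SharingPolicy.separate()):
            lls.append(fit_codon_partitioned(tree, aln, spec, pol,
                                             tol=1e-3).loglik)
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-3

    def test_scaling_factor_recovery(self, codon_sim):
        tree, aln = codon_sim
        fit = fit_codon_partitioned(tree, aln, ModelSpec("HKY"),
                                    SharingPolicy.rates(), tol=1e-3)
        ratio = fit.scaling_factors[2] / fit.scaling_factors[0]
        assert ratio == pytest.approx(3.0, rel=0.10)
        assert fit.scaling_factors[0] == 1.0

    def test_per_site_loglik_sums(self, codon_sim):
        tree, aln = codon_sim
        fit = fit_codon_partitioned(tree, aln, ModelSpec("HKY"),
                                    SharingPolicy.rates(), tol=1e-3)
        vec = fit.per_site_loglik(aln)
        assert vec.sum() == pytest.approx(fit.loglik, abs=1e-5)


@pytest.fixture(scope="module")
def genes():
    tree = pp.read_newick(
            "((A:0.15,B:0.1):0.05,(C:0.12,(D:0.09,E:0.11):0.06):0.05);")
    g1 = simulate_alignment(tree, NucleotideModel.hky(
        np.array([.3, .2, .2, .3]), 1.5), discretize_gamma(0.5, 6),
        900, seed=1, gene_id="g1")
    g2 = simulate_alignment(tree, NucleotideModel.hky(
        np.array([.22, .28, .28, .22]), 4.0), discretize_gamma(0.9, 6),
        900, seed=2, gene_id="g2")
    return tree, [g1, g2]


class TestGenePartitioned:
    def test_single_gene_single_tree_equals_plain_fit(self, genes):
        tree, gs = genes
        res = fit_gene_partitioned([tree], [gs[0]], ModelSpec("HKY"), tol=1e-4)
        plain = optimize_fit(tree, gs[0], ModelSpec("HKY"), tol=1e-4)
        assert res.total_logliks[0] == pytest.approx(plain.loglik, abs=1e-2)

    def test_partitioned_beats_concatenated(self, genes):
        tree, gs = genes
        res = fit_gene_partitioned([tree], gs, ModelSpec("HKY"), tol=1e-4)
        concat = optimize_fit(
            tree, pp.PatternAlignment.concatenate(gs),
            ModelSpec("HKY"), tol=1e-4)
        assert res.total_logliks[0] >= concat.loglik - 1e-3

    def test_gene_order_independence(self, genes):
        tree, gs = genes
        a = fit_gene_partitioned([tree], gs, ModelSpec("HKY"), tol=1e-4)
        b = fit_gene_partitioned([tree], gs[::-1], ModelSpec("HKY"), tol=1e-4)
        assert a.total_logliks[0] == pytest.approx(b.total_logliks[0],
                                                  abs=1e-10)

    def test_site_matrix_shape_and_sum(self, genes):
        tree, gs = genes
        t2 = pp.read_newick(
            "((A:0.1,C:0.1):0.05,(B:0.1,(D:0.1,E:0.1):0.05):0.05);")
        res = fit_gene_partitioned([tree, t2], gs, ModelSpec("HKY"), tol=1e-4)
        assert res.site_loglik_matrix.shape == (2, 1800)
        for i in range(2):
            assert res.site_loglik_matrix[i].sum() == pytest.approx(
                res.total_logliks[i], abs=1e-5)
        assert res.best_index == int(np.argmax(res.total_logliks))

    def test_empty_inputs_rejected(self, genes):
        tree, gs = genes
        with pytest.raises(ValueError):
            fit_gene_partitioned([], gs, ModelSpec("HKY"))
        with pytest.raises(ValueError):
            fit_gene_partitioned([tree], [], ModelSpec("HKY"))

    def test_taxon_mismatch_rejected(self, genes):
        tree, gs = genes
        bad = pp.compress_patterns(list("vwxyz"), ["ACGTAC"] * 5)
        with pytest.raises(ValueError):
            fit_gene_partitioned([tree], [gs[0], bad], ModelSpec("HKY"))


class TestCountFreeParameters:
    def _scheme(self, n_parts, mode, total=600):
        size = total // n_parts
        parts = tuple((f"p{i}", tuple(range(i * size, (i + 1) * size)))
                      for i in range(n_parts))
        return PartitionScheme(parts, mode)

    def test_jc_concatenated_18_taxa(self):
        s = self._scheme(1, PartitionMode.CONCATENATED)
        k, per = count_free_parameters(ModelSpec("JC", gamma=False), 18, s)
        assert (k, per) == (33, [33])

    def test_rev_gamma_concatenated_18_taxa(self):
        s = self._scheme(1, PartitionMode.CONCATENATED)
        k, per = count_free_parameters(ModelSpec("REV", gamma=True), 18, s)
        assert (k, per) == (42, [42])

    def test_by_gene_ten_genes_rev_gamma(self):
        s = self._scheme(10, PartitionMode.BY_GENE)
        k, per = count_free_parameters(ModelSpec("REV", gamma=True), 18, s)
        assert k == 420
        assert per == [42] * 10

    def test_codon_proportional_rates(self):
        s = self._scheme(3, PartitionMode.BY_CODON_POSITION)
        k, _ = count_free_parameters(ModelSpec("REV", gamma=True), 18, s,
                                     SharingPolicy.rates())
        # shared bl 33 + 2 scalers + shared freqs 3 + exch 5 + alpha 1
        assert k == 33 + 2 + 3 + 5 + 1

    def test_codon_separate(self):
        s = self._scheme(3, PartitionMode.BY_CODON_POSITION)
        k, per = count_free_parameters(ModelSpec("REV", gamma=True), 18, s,
                                       SharingPolicy.separate())
        assert per == [42, 42, 42]
        assert k == 126

    def test_lrt_df_chain(self):
        # JC+G -> HKY+G and HKY+G -> REV+G are both df 4
        s = self._scheme(1, PartitionMode.CONCATENATED)
        k_jc, _ = count_free_parameters(ModelSpec("JC", gamma=True), 18, s)
        k_hky, _ = count_free_parameters(ModelSpec("HKY", gamma=True), 18, s)
        k_rev, _ = count_free_parameters(ModelSpec("REV", gamma=True), 18, s)
        assert k_hky - k_jc == 4
        assert k_rev - k_hky == 4

    def test_too_few_taxa(self):
        s = self._scheme(1, PartitionMode.CONCATENATED)
        with pytest.raises(ValueError):
            count_free_parameters(ModelSpec("JC"), 2, s)


class TestPartitionFiles:
    def test_raxml_roundtrip(self, tmp_path):
        p = tmp_path / "parts.txt"
        write_raxml_partitions(p, [("gene1", 1, 300), ("gene2", 301, 450)])
        blocks = read_raxml_partitions(p)
        assert blocks[0][0] == "gene1"
        assert blocks[0][1].tolist() == list(range(0, 300))
        assert blocks[1][1].tolist() == list(range(300, 450))

    def test_raxml_codon_stride(self, tmp_path):
        p = tmp_path / "parts.txt"
        p.write_text("DNA, g1_pos1 = 1-9\\3\n")
        blocks = read_raxml_partitions(p)
        assert blocks[0][1].tolist() == [0, 3, 6]

    def test_raxml_bad_line(self, tmp_path):
        p = tmp_path / "parts.txt"
        p.write_text("PROT, g1 = 1-9\n")
        with pytest.raises(ValueError, match="line 1"):
            read_raxml_partitions(p)

    def test_table_roundtrip_and_labels(self, tmp_path):
        p = tmp_path / "parts.tsv"
        write_partition_table(p, [("g1", 1, 6, 1), ("g2", 7, 12, 1)])
        rows = read_partition_table(p)
        assert rows == [("g1", 1, 6, 1), ("g2", 7, 12, 1)]
        aln = pp.compress_patterns(["a", "b"], ["ACGTACGTACGT"] * 2)
        labeled = apply_partition_labels(aln, rows)
        assert labeled.gene_ids == ["g1"] * 6 + ["g2"] * 6
        assert labeled.codon_positions.tolist() == [1, 2, 3] * 4

    def test_labels_must_cover(self):
        aln = pp.compress_patterns(["a", "b"], ["ACGTAC"] * 2)
        with pytest.raises(ValueError, match="cover"):
            apply_partition_labels(aln, [("g1", 1, 3, 1)])
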