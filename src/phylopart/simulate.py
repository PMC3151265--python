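"""Forward simulation of nucleotide alignments and heterogeneous gene sets.

Genes are simulated under REV(+gamma) processes whose average
transition/transversion ratio R, gamma shape alpha and GC content are drawn
from configurable ranges, emulating realistic inter-gene heterogeneity.
GC is controlled through strand-symmetric frequencies (A=T, C=G); R is
matched exactly by scaling the two transition exchangeabilities jointly
while transversions stay at 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment import PatternAlignment, write_fasta, write_phylip
from .models import (GammaRateModel, NucleotideModel, SpectralDecomposition,
                     average_ts_tv_ratio, build_generator, discretize_gamma)
from .partitions import write_partition_table
from .trees import Node, Tree, enumerate_resolutions, read_newick, write_tree_file

__all__ = ["HeterogeneityProfile", "SimulatedGeneSet", "simulate_alignment",
           "rev_model_with_R", "simulate_heterogeneous_gene_set",
           "make_default_fixture", "DefaultFixture"]


@dataclass(frozen=True)
class HeterogeneityProfile:
    """Per-gene parameter ranges for heterogeneous multigene simulation."""
    r_range: Tuple[float, float] = (1.30, 4.22)
    alpha_range: Tuple[float, float] = (0.25, 1.03)
    gc_range: Tuple[float, float] = (0.38, 0.47)
    gene_length_range: Tuple[int, int] = (100, 800)  # codons
    codon_rate_multipliers: Tuple[float, float, float] = (1.0, 0.5, 3.0)
    n_genes: int = 20

    def __post_init__(self):
        for name in ("r_range", "alpha_range", "gc_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive ordered interval")
        if any(m <= 0 for m in self.codon_rate_multipliers):
            raise ValueError("codon rate multipliers must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class SimulatedGeneSet:
    """Simulated gene alignments with the generating truth."""
    genes: List[PatternAlignment]
    true_tree: Tree
    true_params: List[dict]
    seed: Optional[int] = None

    def supermatrix(self) -> PatternAlignment:
        return PatternAlignment.concatenate(self.genes)

    def write(self, outdir) -> dict:
        """Write FASTA per gene, PHYLIP supermatrix, partition table, truth."""
        os.makedirs(outdir, exist_ok=True)
        paths = {"genes": []}
        rows = []
        offset = 1
        for g in self.genes:
            name = g.gene_ids[0]
            p = os.path.join(outdir, f"{name}.fasta")
            write_fasta(p, g)
            paths["genes"].append(p)
            rows.append((name, offset, offset + g.total_length - 1, 1))
            offset += g.total_length
        if self.genes:
            sm = self.supermatrix()
            paths["supermatrix"] = os.path.join(outdir, "supermatrix.phy")
            write_phylip(paths["supermatrix"], sm)
        paths["partitions"] = os.path.join(outdir, "partitions.tsv")
        write_partition_table(paths["partitions"], rows)
        paths["true_tree"] = os.path.join(outdir, "true_tree.nwk")
        write_tree_file(paths["true_tree"], [self.true_tree])
        paths["truth"] = os.path.join(outdir, "truth.tsv")
        with open(paths["truth"], "w") as fh:
            cols = ["gene", "length_nt", "R", "alpha", "gc",
                    "mult1", "mult2", "mult3"]
            fh.write("\t".join(cols) + "\n")
            for row in self.true_params:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        return paths


def simulate_alignment(tree: Tree, model: NucleotideModel,
                       gamma: Optional[GammaRateModel], length: int,
                       position_multipliers: Optional[Sequence[float]] = None,
                       seed=None, rng: Optional[np.random.Generator] = None,
                       gene_id: str = "gene1") -> PatternAlignment:
    """Simulate an ungapped alignment down a tree with branch lengths.

    Root states are drawn from the stationary frequencies; each site evolves
    at rate (gamma category draw) x (codon-position multiplier).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    for n in tree.root.walk_postorder():
        if n is not tree.root and n.length is None:
            raise ValueError("tree must have branch lengths for simulation")

    spectral = SpectralDecomposition(build_generator(model), model.frequencies)
    if gamma is not None:
        cat = rng.integers(gamma.n_categories, size=length)
        site_rate = gamma.category_rates[cat]
    else:
        site_rate = np.ones(length)
    codon_pos = np.zeros(length, dtype=np.int8)
    if length % 3 == 0:
        codon_pos = (np.arange(length) % 3 + 1).astype(np.int8)
    if position_multipliers is not None:
        if length % 3 != 0:
            raise ValueError("position multipliers need length divisible by 3")
        mult = np.asarray(position_multipliers, float)
        site_rate = site_rate * mult[np.arange(length) % 3]

    classes, class_of = np.unique(site_rate, return_inverse=True)
    states = {id(tree.root): rng.choice(4, size=length, p=model.frequencies)}
    order = [n for n in tree.root.walk_postorder()][::-1]  # preorder
    for node in order:
        parent_states = states[id(node)]
        for child in node.children:
            out = np.empty(length, dtype=np.int64)
            for ci, rate in enumerate(classes):
                P = spectral.probabilities(rate * child.length)
                P = P / P.sum(axis=1, keepdims=True)
                for s in range(4):
                    mask = (class_of == ci) & (parent_states == s)
                    k = int(mask.sum())
                    if k:
                        out[mask] = rng.choice(4, size=k, p=P[s])
            states[id(child)] = out

    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    taxa, seqs = [], []
    for node in tree.root.walk_postorder():
        if node.is_leaf:
            taxa.append(node.label)
            seqs.append(alphabet[states[id(node)]].tobytes().decode("ascii"))
    return PatternAlignment.from_sequences(
        taxa, seqs, gene_ids=[gene_id] * length, codon_positions=codon_pos)


def rev_model_with_R(gc: float, R: float) -> NucleotideModel:
    """REV model with strand-symmetric frequencies hitting GC and R exactly.

    Transversions stay at 1; the two transition exchangeabilities are set to
    the value that makes the stationary-flux ratio equal R (a linear solve,
    since R is proportional to the joint transition scaling).
    """
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    a = (1.0 - gc) / 2.0
    g = gc / 2.0
    pi = np.array([a, g, g, a])  # A, C, G, T with A=T and C=G
    num = pi[0] * pi[2] + pi[1] * pi[3]
    den = (pi[0] * pi[1] + pi[0] * pi[3] + pi[1] * pi[2] + pi[2] * pi[3])
    s = R * den / num
    if not (1e-4 <= s <= 1e4):
        raise ValueError(f"requested R={R} needs transition scaling {s} "
                         "outside the supported range")
    exch = np.array([1.0, s, 1.0, 1.0, s, 1.0])
    return NucleotideModel.rev(pi, exch)


def simulate_heterogeneous_gene_set(tree: Tree, profile: HeterogeneityProfile,
                                    seed=None,
                                    rng: Optional[np.random.Generator] = None
                                    ) -> SimulatedGeneSet:
    """Simulate n_genes genes with per-gene (R, alpha, GC, length) draws."""
    if rng is None:
        rng = np.random.default_rng(seed)
    genes, truth = [], []
    for gi in range(profile.n_genes):
        alpha = float(rng.uniform(*profile.alpha_range))
        gc = float(rng.uniform(*profile.gc_range))
        R = float(rng.uniform(*profile.r_range))
        codons = int(rng.integers(profile.gene_length_range[0],
                                  profile.gene_length_range[1] + 1))
        length = 3 * codons
        model = rev_model_with_R(gc, R)
        gamma = discretize_gamma(alpha, 6)
        name = f"gene{gi + 1:03d}"
        aln = simulate_alignment(tree, model, gamma, length,
                                 position_multipliers=profile.codon_rate_multipliers,
                                 rng=rng, gene_id=name)
        genes.append(aln)
        m1, m2, m3 = profile.codon_rate_multipliers
        truth.append({"gene": name, "length_nt": length, "R": R,
                      "alpha": alpha, "gc": gc,
                      "mult1": m1, "mult2": m2, "mult3": m3})
        assert abs(average_ts_tv_ratio(model) - R) < 1e-9
    return SimulatedGeneSet(genes, true_tree=tree.copy(), true_params=truth,
                            seed=seed)


# ---------------------------------------------------------------------
# Default end-to-end fixture


@dataclass
class DefaultFixture:
    gene_set: SimulatedGeneSet
    true_tree: Tree
    backbone: Tree
    candidate_trees: List[Tree]
    seed: int


def _clade7() -> str:
    return "(((A1,A2),(A3,A4)),((A5,A6),A7))"


def _clade4() -> str:
    return "((B1,B2),(B3,B4))"


def _clade6() -> str:
    return "((C1,(C2,C3)),((C4,C5),C6))"


def make_default_fixture(seed: int, n_genes: int = 8,
                         profile: Optional[HeterogeneityProfile] = None
                         ) -> DefaultFixture:
    """18-taxon fixture: true tree, polytomous backbone, candidate set, genes.

    The true tree has an outgroup plus clades of 7, 4 and 6 taxa.  The
    backbone collapses one region in the 7-clade to a 4-way polytomy (15
    resolutions) and one region in the 6-clade to a 3-way polytomy (3
    resolutions), giving a 45-tree candidate set that contains the truth.
    """
    rng = np.random.default_rng(seed)
    topo = f"(OUT,({_clade7()},({_clade4()},{_clade6()})));"
    true_tree = read_newick(topo)
    for node in true_tree.root.walk_postorder():
        if node is true_tree.root:
            continue
        if node.is_leaf:
            node.length = float(rng.uniform(0.06, 0.25))
        else:
            node.length = float(rng.uniform(0.04, 0.12))
    # longer outgroup branch
    for node in true_tree.root.children:
        if node.is_leaf and node.label == "OUT":
            node.length = 0.45

    backbone = read_newick(
        "(OUT,(((A1,A2),(A3,A4),(A5,A6),A7),"
        f"({_clade4()},((C1,C2,C3),((C4,C5),C6)))));")
    candidates = enumerate_resolutions(backbone)

    prof = profile or HeterogeneityProfile(n_genes=n_genes)
    if prof.n_genes != n_genes:
        prof = HeterogeneityProfile(
            r_range=prof.r_range, alpha_range=prof.alpha_range,
            gc_range=prof.gc_range, gene_length_range=prof.gene_length_range,
            codon_rate_multipliers=prof.codon_rate_multipliers,
            n_genes=n_genes)
    gene_set = simulate_heterogeneous_gene_set(true_tree, prof, rng=rng)
    gene_set.seed = seed
    return DefaultFixture(gene_set=gene_set, true_tree=true_tree,
                          backbone=backbone, candidate_trees=candidates,
                          seed=seed)
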