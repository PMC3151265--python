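"""Partition schemes and partitioned maximum-likelihood fitting.

Covers the codon-position sharing ladder (proportional branch-length
scaling factors through fully separate per-position parameter sets), gene
partitioning where every gene gets its own parameters and the total
likelihood of a candidate topology is the sum of per-gene maxima, and the
exact free-parameter accounting used by the model-selection tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as _opt

from .alignment import PatternAlignment
from .likelihood import (FittedModel, ModelSpec, _branch_sweep, _Engine,
                         _pack_model, _Structure, count_free_parameters_single,
                         optimize_fit, per_site_log_likelihoods)
from .models import ModelKind, NucleotideModel, discretize_gamma
from .trees import Tree

__all__ = [
    "PartitionMode", "PartitionScheme", "SharingPolicy",
    "split_codon_positions", "fit_codon_partitioned", "fit_gene_partitioned",
    "count_free_parameters", "CodonPartitionedFit", "GenePartitionedResult",
    "read_raxml_partitions", "write_raxml_partitions",
    "read_partition_table", "write_partition_table", "apply_partition_labels",
]


class PartitionMode(str, Enum):
    CONCATENATED = "concatenated"
    BY_CODON_POSITION = "by_codon_position"
    BY_GENE = "by_gene"
    BY_GENE_AND_CODON_POSITION = "by_gene_and_codon_position"


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered disjoint site partitions covering the whole alignment."""
    partitions: Tuple[Tuple[str, tuple], ...]
    mode: PartitionMode

    def __post_init__(self):
        # coverage of the full site range is validated in `for_alignment`
        seen = set()
        for name, idx in self.partitions:
            if len(idx) == 0:
                raise ValueError(f"empty partition {name!r}")
            if seen & set(idx):
                raise ValueError(f"partition {name!r} overlaps another")
            seen |= set(idx)

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.partitions]

    def sizes(self) -> List[int]:
        return [len(idx) for _, idx in self.partitions]

    @classmethod
    def for_alignment(cls, data: PatternAlignment,
                      mode: PartitionMode) -> "PartitionScheme":
        mode = PartitionMode(mode)
        n = data.total_length
        genes = list(dict.fromkeys(data.gene_ids))
        gene_idx = {g: [] for g in genes}
        for i, g in enumerate(data.gene_ids):
            gene_idx[g].append(i)
        parts: List[Tuple[str, tuple]] = []
        if mode == PartitionMode.CONCATENATED:
            parts = [("all", tuple(range(n)))]
        elif mode == PartitionMode.BY_GENE:
            parts = [(g, tuple(gene_idx[g])) for g in genes]
        elif mode == PartitionMode.BY_CODON_POSITION:
            for k in (1, 2, 3):
                idx = tuple(np.flatnonzero(data.codon_positions == k))
                parts.append((f"pos{k}", idx))
        else:
            for g in genes:
                gi = np.array(gene_idx[g])
                for k in (1, 2, 3):
                    idx = tuple(gi[data.codon_positions[gi] == k])
                    parts.append((f"{g}_pos{k}", idx))
        covered = sum(len(i) for _, i in parts)
        if covered != n:
            raise ValueError(
                f"{mode.value} scheme covers {covered} of {n} sites "
                "(missing codon-position labels?)")
        return cls(tuple(parts), mode)


@dataclass(frozen=True)
class SharingPolicy:
    """Which codon-position parameters are shared, proportional, or free.

    The ladder, in increasing generality:

    ==================  ==============================================
    shared()            everything shared (equals the concatenated fit)
    rates()             proportional branch lengths via scaling factors
    rates_freqs()       + separate nucleotide frequencies per position
    rates_exch()        + separate exchangeabilities (kappa for HKY)
    rates_freqs_exch()  + both
    separate()          fully separate branch lengths and parameters
    ==================  ==============================================

    ``separate_branch_lengths`` supersedes proportional scaling; with it the
    three positions are fitted entirely independently (including alpha).
    The reference scaling factor (position 1) is fixed at 1.
    """
    proportional_rates: bool = False
    separate_frequencies: bool = False
    separate_exchangeabilities: bool = False
    separate_branch_lengths: bool = False
    per_gene_alpha: bool = True

    LADDER = ("shared", "rates", "rates+freqs", "rates+exch",
              "rates+freqs+exch", "separate")

    @classmethod
    def shared(cls): return cls()

    @classmethod
    def rates(cls): return cls(proportional_rates=True)

    @classmethod
    def rates_freqs(cls):
        return cls(proportional_rates=True, separate_frequencies=True)

    @classmethod
    def rates_exch(cls):
        return cls(proportional_rates=True, separate_exchangeabilities=True)

    @classmethod
    def rates_freqs_exch(cls):
        return cls(proportional_rates=True, separate_frequencies=True,
                   separate_exchangeabilities=True)

    @classmethod
    def separate(cls):
        return cls(separate_frequencies=True, separate_exchangeabilities=True,
                   separate_branch_lengths=True)

    @classmethod
    def from_label(cls, label: str) -> "SharingPolicy":
        table = {
            "shared": cls.shared, "rates": cls.rates,
            "rates+freqs": cls.rates_freqs, "rates+exch": cls.rates_exch,
            "rates+freqs+exch": cls.rates_freqs_exch, "separate": cls.separate,
        }
        if label not in table:
            raise ValueError(f"unknown policy {label!r}; one of {sorted(table)}")
        return table[label]()

    @property
    def label(self) -> str:
        if self.separate_branch_lengths:
            return "separate"
        if not self.proportional_rates:
            return "shared"
        tag = "rates"
        if self.separate_frequencies:
            tag += "+freqs"
        if self.separate_exchangeabilities:
            tag += "+exch"
        return tag

    @property
    def is_trivial(self) -> bool:
        return self.label == "shared"


def split_codon_positions(data: PatternAlignment) -> List[np.ndarray]:
    """Site-index sets for codon positions 1, 2, 3 (frame starts at site 1)."""
    n = data.total_length
    if n % 3 != 0:
        raise ValueError(f"alignment length {n} is not divisible by 3")
    if np.any(data.codon_positions > 0):
        out = [np.flatnonzero(data.codon_positions == k) for k in (1, 2, 3)]
    else:
        sites = np.arange(n)
        out = [sites[sites % 3 == k] for k in (0, 1, 2)]
    if len({len(o) for o in out}) != 1:
        raise ValueError("codon positions are not equally represented")
    return out


# ---------------------------------------------------------------------
# Codon-position partitioned fitting


@dataclass
class CodonPartitionedFit:
    """Joint fit over codon-position partitions under a sharing policy.

    ``position_fits[k]`` carries position k's effective parameters; its
    topology holds the *effective* branch lengths (shared lengths times the
    position's scaling factor, or its own lengths under ``separate``).
    """
    position_fits: List[FittedModel]
    position_sites: List[np.ndarray]
    scaling_factors: np.ndarray
    policy: SharingPolicy
    spec: ModelSpec
    loglik: float
    n_free_params: int
    converged: bool

    def per_site_loglik(self, data: PatternAlignment) -> np.ndarray:
        out = np.empty(data.total_length)
        for fit, idx in zip(self.position_fits, self.position_sites):
            out[idx] = per_site_log_likelihoods(fit, data.subset_sites(idx))
        return out


def _combine_model(kind: ModelKind, own: NucleotideModel,
                   shared: NucleotideModel, policy: SharingPolicy
                   ) -> NucleotideModel:
    freqs = own.frequencies if policy.separate_frequencies else shared.frequencies
    if kind == ModelKind.JC:
        return NucleotideModel.jc()
    if kind == ModelKind.HKY:
        kappa = own.kappa if policy.separate_exchangeabilities else shared.kappa
        return NucleotideModel.hky(freqs, kappa)
    exch = (own.exchangeabilities if policy.separate_exchangeabilities
            else shared.exchangeabilities)
    return NucleotideModel.rev(freqs, exch)


def fit_codon_partitioned(tree: Tree, data: PatternAlignment, spec: ModelSpec,
                          policy: SharingPolicy, *, tol: float = 1e-6,
                          max_sweeps: int = 200,
                          param_maxiter: int = 40) -> CodonPartitionedFit:
    """Fit the codon-position ladder on a fixed topology."""
    sites = split_codon_positions(data)
    parts = [data.subset_sites(idx) for idx in sites]
    n_taxa = len(data.taxa)

    if policy.is_trivial:
        base = optimize_fit(tree, data, spec, tol=tol, max_sweeps=max_sweeps,
                            param_maxiter=param_maxiter)
        fits = [FittedModel(base.topology, base.model, base.gamma,
                            float(per_site_log_likelihoods(base, p).sum()),
                            base.n_free_params, base.converged)
                for p in parts]
        return CodonPartitionedFit(
            fits, sites, np.ones(3), policy, spec, base.loglik,
            count_free_parameters(spec, n_taxa,
                                  PartitionScheme.for_alignment(
                                      data, PartitionMode.CONCATENATED),
                                  policy)[0],
            base.converged)

    if policy.separate_branch_lengths:
        fits = [optimize_fit(tree, p, spec, tol=tol, max_sweeps=max_sweeps,
                             param_maxiter=param_maxiter) for p in parts]
        total = sum(f.loglik for f in fits)
        k = sum(f.n_free_params for f in fits)
        return CodonPartitionedFit(fits, sites, np.ones(3), policy, spec,
                                   total, k, all(f.converged for f in fits))

    # proportional branch lengths, optionally separate freqs/exchangeabilities
    S = _Structure(tree)
    lengths = S.lengths.copy()
    lengths[:] = 0.1
    lengths[S.root] = 0.0
    scales = np.ones(3)
    gamma = discretize_gamma(0.5, spec.n_categories) if spec.gamma else None
    models = []
    for p in parts:
        if spec.kind == ModelKind.JC:
            models.append(NucleotideModel.jc())
        elif spec.kind == ModelKind.HKY:
            models.append(NucleotideModel.hky(
                p.empirical_frequencies() if policy.separate_frequencies
                else data.empirical_frequencies(), 2.0))
        else:
            models.append(NucleotideModel.rev(
                p.empirical_frequencies() if policy.separate_frequencies
                else data.empirical_frequencies(), np.ones(6)))
    engines = [_Engine(S, p, m, gamma) for p, m in zip(parts, models)]

    def total_ll() -> float:
        return sum(e.loglik_at(lengths * c) for e, c in zip(engines, scales))

    def optimize_scale(k: int) -> None:
        e = engines[k]

        def neg(c: float) -> float:
            return -e.loglik_at(lengths * c)

        cur = neg(scales[k])
        res = _opt.minimize_scalar(neg, bounds=(1e-3, 1e3), method="bounded",
                                   options={"xatol": 1e-7})
        if res.fun < cur:
            scales[k] = float(res.x)

    def separate_param_step() -> None:
        for k, e in enumerate(engines):
            x0, bounds, unpack = _pack_model(
                e.model, None,
                include_freqs=policy.separate_frequencies,
                include_exch=policy.separate_exchangeabilities,
                include_alpha=False)
            if x0.size == 0:
                continue

            def neg(x):
                m, _ = unpack(x)
                e.set_model(m, e.gamma)
                return -e.loglik_at(lengths * scales[k])

            res = _opt.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": param_maxiter})
            x = res.x if res.fun <= neg(x0) else x0
            m, _ = unpack(x)
            e.set_model(m, e.gamma)
            e.loglik_at(lengths * scales[k])

    def shared_param_step() -> None:
        nonlocal gamma
        alpha = gamma.alpha if gamma is not None else None
        x0, bounds, unpack = _pack_model(
            engines[0].model, alpha,
            include_freqs=not policy.separate_frequencies,
            include_exch=not policy.separate_exchangeabilities,
            include_alpha=spec.gamma)
        if x0.size == 0:
            return
        own = [e.model for e in engines]

        def apply(x) -> float:
            shared_m, a = unpack(x)
            g = discretize_gamma(a, spec.n_categories) if a is not None else None
            tot = 0.0
            for k, e in enumerate(engines):
                e.set_model(_combine_model(spec.kind, own[k], shared_m, policy), g)
                tot += e.loglik_at(lengths * scales[k])
            return tot

        cur = apply(x0)
        res = _opt.minimize(lambda x: -apply(x), x0, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": param_maxiter})
        best = res.x if -res.fun >= cur else x0
        apply(best)
        if spec.gamma:
            _, a = unpack(best)
            gamma = discretize_gamma(a, spec.n_categories)

    ll = total_ll()
    converged = False
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        _branch_sweep(engines, lengths, scales)
        if policy.proportional_rates:
            for k in (1, 2):
                optimize_scale(k)
        separate_param_step()
        shared_param_step()
        new_ll = total_ll()
        if new_ll - ll < tol:
            ll = max(ll, new_ll)
            converged = True
            break
        ll = new_ll

    scheme = PartitionScheme.for_alignment(data, PartitionMode.BY_CODON_POSITION)
    k_total, _ = count_free_parameters(spec, n_taxa, scheme, policy)
    fits = []
    for k, e in enumerate(engines):
        t_k = S.to_tree(lengths * scales[k])
        fits.append(FittedModel(t_k, e.model, e.gamma,
                                float(e.loglik_at(lengths * scales[k])),
                                count_free_parameters_single(spec, n_taxa),
                                converged))
    return CodonPartitionedFit(fits, sites, scales.copy(), policy, spec,
                               ll, k_total, converged)


# ---------------------------------------------------------------------
# Gene-partitioned supermatrix fitting


@dataclass
class GenePartitionedResult:
    """Exhaustive scoring of a candidate tree set under gene partitioning."""
    trees: List[Tree]
    total_logliks: np.ndarray          # (n_trees,)
    site_loglik_matrix: np.ndarray     # (n_trees, n_sites), gene-concatenated
    best_index: int
    best_gene_fits: list               # per-gene FittedModel/CodonPartitionedFit
    gene_names: List[str]
    gene_logliks: np.ndarray           # (n_trees, n_genes)
    n_free_params: int
    converged: bool

    @property
    def best_tree(self) -> Tree:
        return self.trees[self.best_index]


def fit_gene_partitioned(candidate_trees: Sequence[Tree],
                         genes: Sequence[PatternAlignment], spec: ModelSpec,
                         policy: Optional[SharingPolicy] = None, *,
                         tol: float = 1e-5, max_sweeps: int = 200,
                         param_maxiter: int = 40) -> GenePartitionedResult:
    """Score every candidate topology as the sum of independent per-gene fits.

    Each gene receives its own branch lengths, frequencies, exchangeabilities
    and alpha (crossed with the codon-position ``policy`` when one is given).
    """
    if not candidate_trees:
        raise ValueError("empty candidate tree set")
    if not genes:
        raise ValueError("no genes to fit")
    taxa = set(genes[0].taxa)
    for g in genes[1:]:
        if set(g.taxa) != taxa:
            raise ValueError("genes disagree on the taxon set")
    for t in candidate_trees:
        if set(t.taxa) != taxa:
            raise ValueError("candidate tree does not span the gene taxon set")

    n_trees = len(candidate_trees)
    n_genes = len(genes)
    gene_names = [g.gene_ids[0] for g in genes]
    sizes = [g.total_length for g in genes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    site_ll = np.zeros((n_trees, int(offsets[-1])))
    gene_ll = np.zeros((n_trees, n_genes))
    all_fits: List[list] = [[None] * n_genes for _ in range(n_trees)]
    warm: List[Optional[FittedModel]] = [None] * n_genes

    use_codon = policy is not None and not policy.is_trivial
    for ti, tree in enumerate(candidate_trees):
        for gi, g in enumerate(genes):
            if use_codon:
                fit = fit_codon_partitioned(tree, g, spec, policy, tol=tol,
                                            max_sweeps=max_sweeps,
                                            param_maxiter=param_maxiter)
                vec = fit.per_site_loglik(g)
                gene_ll[ti, gi] = fit.loglik
            else:
                init_m = warm[gi].model if warm[gi] is not None else None
                init_a = warm[gi].alpha if warm[gi] is not None else None
                fit = optimize_fit(tree, g, spec, tol=tol,
                                   max_sweeps=max_sweeps,
                                   param_maxiter=param_maxiter,
                                   init_model=init_m, init_alpha=init_a)
                warm[gi] = fit
                vec = per_site_log_likelihoods(fit, g)
                gene_ll[ti, gi] = fit.loglik
            all_fits[ti][gi] = fit
            site_ll[ti, offsets[gi]:offsets[gi + 1]] = vec

    totals = gene_ll.sum(axis=1)
    best = int(np.argmax(totals))
    if use_codon:
        k_per_gene = [f.n_free_params for f in all_fits[best]]
        conv = all(f.converged for row in all_fits for f in row)
    else:
        k_per_gene = [f.n_free_params for f in all_fits[best]]
        conv = all(f.converged for row in all_fits for f in row)
    return GenePartitionedResult(
        trees=list(candidate_trees), total_logliks=totals,
        site_loglik_matrix=site_ll, best_index=best,
        best_gene_fits=all_fits[best], gene_names=gene_names,
        gene_logliks=gene_ll, n_free_params=int(sum(k_per_gene)),
        converged=conv)


# ---------------------------------------------------------------------
# Free-parameter accounting


def count_free_parameters(spec: ModelSpec, n_taxa: int,
                          scheme: PartitionScheme,
                          policy: Optional[SharingPolicy] = None
                          ) -> Tuple[int, List[int]]:
    """Total free parameters K and the per-partition K_i decomposition.

    Blocks: branch lengths 2n-3 per independent set; frequencies 3;
    REV exchangeabilities 5 (HKY kappa 1); alpha 1; proportional scaling
    factors (#positions - 1) per shared-branch-length codon scheme.  Shared
    blocks are attributed to the first partition of their group.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    policy = policy or SharingPolicy.shared()
    bl = 2 * n_taxa - 3
    freq = 0 if spec.kind == ModelKind.JC else 3
    exch = {ModelKind.JC: 0, ModelKind.HKY: 1, ModelKind.REV: 5}[spec.kind]
    al = 1 if spec.gamma else 0
    mode = scheme.mode

    def codon_group_counts() -> List[int]:
        if policy.separate_branch_lengths:
            return [bl + freq + exch + al] * 3
        k1 = bl + al  # shared branch lengths and alpha, attributed to pos 1
        if policy.proportional_rates:
            k1 += 2
        per = []
        for k in range(3):
            kk = 0
            if policy.separate_frequencies:
                kk += freq
            if policy.separate_exchangeabilities:
                kk += exch
            per.append(kk)
        if not policy.separate_frequencies:
            k1 += freq
        if not policy.separate_exchangeabilities:
            k1 += exch
        per[0] += k1
        return per

    if mode == PartitionMode.CONCATENATED:
        per = [bl + freq + exch + al]
    elif mode == PartitionMode.BY_GENE:
        per = [bl + freq + exch + al for _ in scheme.partitions]
    elif mode == PartitionMode.BY_CODON_POSITION:
        per = codon_group_counts()
    else:  # by gene and codon position: the codon scheme replicated per gene
        n_genes = len(scheme.partitions) // 3
        per = []
        for _ in range(n_genes):
            per.extend(codon_group_counts())
    return int(sum(per)), [int(x) for x in per]


# ---------------------------------------------------------------------
# Partition file formats (1-based inclusive coordinates)

_RAXML_RE = re.compile(
    r"^\s*DNA\s*,\s*(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)"
    r"\s*(?P<codon>\\3)?\s*$", re.IGNORECASE)


def read_raxml_partitions(path) -> List[Tuple[str, np.ndarray]]:
    """RAxML-style lines ``DNA, <name> = <start>-<end>[\\3]`` (1-based)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            m = _RAXML_RE.match(line)
            if not m:
                raise ValueError(f"bad partition line {lineno}: {line!r}")
            start, end = int(m["start"]), int(m["end"])
            if not (1 <= start <= end):
                raise ValueError(f"bad coordinates on line {lineno}")
            if m["codon"]:
                idx = np.arange(start - 1, end, 3)
            else:
                idx = np.arange(start - 1, end)
            out.append((m["name"], idx))
    return out


def write_raxml_partitions(path, blocks: Sequence[Tuple[str, int, int]]) -> None:
    """Write contiguous (name, start, end) blocks, 1-based inclusive."""
    with open(path, "w") as fh:
        for name, start, end in blocks:
            fh.write(f"DNA, {name} = {start}-{end}\n")


def read_partition_table(path) -> List[Tuple[str, int, int, int]]:
    """Native TSV: gene, start, end, frame (all 1-based, frame in 1..3)."""
    out = []
    with open(path) as fh:
        header = fh.readline().split("\t")
        for line in fh:
            if not line.strip():
                continue
            gene, start, end, frame = line.rstrip("\n").split("\t")
            out.append((gene, int(start), int(end), int(frame)))
    return out


def write_partition_table(path, rows: Sequence[Tuple[str, int, int, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\tframe\n")
        for gene, start, end, frame in rows:
            fh.write(f"{gene}\t{start}\t{end}\t{frame}\n")


def apply_partition_labels(data: PatternAlignment,
                           rows: Sequence[Tuple[str, int, int, int]]
                           ) -> PatternAlignment:
    """Label sites with gene ids and codon positions from a partition table."""
    genes = ["?"] * data.total_length
    pos = np.zeros(data.total_length, dtype=np.int8)
    for gene, start, end, frame in rows:
        for i in range(start - 1, end):
            genes[i] = gene
            pos[i] = ((i - (start - 1) + (frame - 1)) % 3) + 1
    if "?" in genes:
        raise ValueError("partition table does not cover every site")
    return PatternAlignment(data.taxa, data.patterns, data.weights,
                            data.site_to_pattern, gene_ids=genes,
                            codon_positions=pos)
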