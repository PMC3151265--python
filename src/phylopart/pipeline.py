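"""High-level analysis drivers shared by the CLI and by scripted use.

Two analyses: per-gene tree estimation with hierarchical model choice and
congruence diagnostics, and exhaustive supermatrix scoring of a candidate
tree set under a ladder of codon-position/gene partition models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import PatternAlignment
from .likelihood import FittedModel, ModelSpec, optimize_fit, \
    per_site_log_likelihoods
from .models import average_ts_tv_ratio
from .partitions import (CodonPartitionedFit, PartitionMode, PartitionScheme,
                         SharingPolicy, count_free_parameters,
                         fit_codon_partitioned, fit_gene_partitioned)
from .search import nni_hill_climb
from .selection import (CongruenceSummary, ModelComparisonRow, RellResult,
                        aicc_partitioned, bic_partitioned, congruence_summary,
                        hierarchical_gene_model_test, likelihood_ratio_test,
                        parameter_heterogeneity_summary, rell_bootstrap)
from .trees import Tree, random_topology

__all__ = ["GeneTreeRun", "run_genetrees", "SupermatrixCell",
           "score_candidates", "run_supermatrix_ladder"]


# ---------------------------------------------------------------------
# Single-gene pipeline


@dataclass
class GeneTreeRun:
    table: pd.DataFrame           # gene, best_model, loglik, R, alpha, gc, ...
    trees: Dict[str, Tree]
    congruence: Optional[CongruenceSummary]
    excluded: List[str]           # genes dropped for non-convergence


def run_genetrees(genes: Sequence[PatternAlignment], *, seed=None,
                  n_null_sims: int = 1000, tol: float = 1e-4,
                  search_tol: float = 1e-2,
                  start_tree: Optional[Tree] = None) -> GeneTreeRun:
    """Per-gene ML trees (NNI search under REV+G), model choice, congruence.

    Unconverged genes are flagged, excluded from the congruence and
    heterogeneity summaries, and reported in ``excluded``.
    """
    rng = np.random.default_rng(seed)
    rows, trees, excluded = [], {}, []
    fits, alns = [], []
    rev = ModelSpec("REV", gamma=True)
    for g in genes:
        name = g.gene_ids[0]
        start = start_tree or random_topology(sorted(g.taxa), rng=rng)
        searched = nni_hill_climb(g, rev, start, tol=search_tol,
                                  neighbor_max_sweeps=12)
        test = hierarchical_gene_model_test(g, searched.topology, tol=tol)
        best_fit = test.fits[test.best.kind.value]
        if not (searched.converged and best_fit.converged):
            excluded.append(name)
            continue
        rev_fit = test.fits["REV"]
        trees[name] = searched.topology
        rows.append({
            "gene": name, "best_model": test.best.label,
            "loglik": best_fit.loglik,
            "p_jc_vs_hky": test.p_jc_vs_hky,
            "p_hky_vs_rev": test.p_hky_vs_rev,
            "R": average_ts_tv_ratio(rev_fit.model),
            "alpha": rev_fit.alpha, "gc": g.gc_content(),
        })
        fits.append(rev_fit)
        alns.append(g)
    table = pd.DataFrame(rows)
    cong = None
    if len(trees) >= 2:
        cong = congruence_summary(list(trees.values()), n_sims=n_null_sims,
                                  seed=rng.integers(2 ** 31))
    return GeneTreeRun(table=table, trees=trees, congruence=cong,
                       excluded=excluded)


# ---------------------------------------------------------------------
# Supermatrix pipeline


@dataclass
class SupermatrixCell:
    """One (model, policy, mode) cell of the comparison ladder."""
    spec: ModelSpec
    policy: SharingPolicy
    mode: str                      # "concat" | "by-gene"
    total_logliks: np.ndarray      # per candidate tree
    best_index: int
    loglik: float
    k_total: int
    k_per_partition: List[int]
    n_per_partition: List[int]
    site_loglik_matrix: Optional[np.ndarray] = None
    label: str = ""

    @property
    def aicc(self) -> float:
        return aicc_partitioned(self.loglik, self.k_per_partition,
                                self.n_per_partition)

    @property
    def bic(self) -> float:
        return bic_partitioned(self.loglik, self.k_per_partition,
                               self.n_per_partition)


def _prescreened_gene_scoring(candidate_trees, genes, spec, tol,
                              param_maxiter, refit_top):
    """Two-stage exhaustive scoring of a large candidate set.

    Stage 1 freezes each gene's substitution parameters at the estimates
    from the first candidate and optimizes branch lengths only (cheap but
    slightly pessimistic for every tree equally); stage 2 fully re-optimizes
    the top ``refit_top`` trees, which decides the winner exactly.
    """
    sizes = [g.total_length for g in genes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    base = [optimize_fit(candidate_trees[0], g, spec, tol=tol,
                         param_maxiter=param_maxiter) for g in genes]
    n_trees = len(candidate_trees)
    totals = np.zeros(n_trees)
    site_m = np.zeros((n_trees, int(offsets[-1])))
    screen_tol = max(tol, 1e-2)
    for ti, tree in enumerate(candidate_trees):
        for gi, g in enumerate(genes):
            fit = optimize_fit(tree, g, spec, tol=screen_tol, max_sweeps=15,
                               init_model=base[gi].model,
                               init_alpha=base[gi].alpha, fit_params=False)
            vec = per_site_log_likelihoods(fit, g)
            site_m[ti, offsets[gi]:offsets[gi + 1]] = vec
            totals[ti] += fit.loglik
    top = np.argsort(totals)[::-1][:refit_top]
    refit = fit_gene_partitioned([candidate_trees[i] for i in top], genes,
                                 spec, None, tol=tol,
                                 param_maxiter=param_maxiter)
    for k, ti in enumerate(top):
        totals[ti] = refit.total_logliks[k]
        site_m[ti] = refit.site_loglik_matrix[k]
    best = int(top[int(np.argmax(refit.total_logliks))])
    return totals, site_m, best


def score_candidates(candidate_trees: Sequence[Tree],
                     supermatrix: PatternAlignment,
                     genes: Sequence[PatternAlignment], spec: ModelSpec,
                     policy: SharingPolicy, mode: str, *,
                     tol: float = 1e-4, param_maxiter: int = 30,
                     keep_site_matrix: bool = True,
                     prescreen: bool = True,
                     refit_top: int = 5) -> SupermatrixCell:
    """Exhaustively score every candidate tree under one ladder cell.

    For plain by-gene partitioning over a candidate set larger than
    ``refit_top``, a two-stage screen (branch lengths only at frozen
    per-gene parameters, then full refits of the leaders) is used unless
    ``prescreen=False``.
    """
    n_taxa = len(supermatrix.taxa)
    if mode == "by-gene":
        if policy.is_trivial and prescreen and \
                len(candidate_trees) > refit_top:
            totals, site_m, best = _prescreened_gene_scoring(
                candidate_trees, genes, spec, tol, param_maxiter, refit_top)
            res = None
        else:
            res = fit_gene_partitioned(
                candidate_trees, genes, spec,
                policy if not policy.is_trivial else None,
                tol=tol, param_maxiter=param_maxiter)
            totals = res.total_logliks
            best = res.best_index
            site_m = res.site_loglik_matrix
        scheme_mode = (PartitionMode.BY_GENE if policy.is_trivial
                       else PartitionMode.BY_GENE_AND_CODON_POSITION)
        scheme = PartitionScheme.for_alignment(supermatrix, scheme_mode)
        k_tot, k_per = count_free_parameters(spec, n_taxa, scheme, policy)
        n_per = scheme.sizes()
    elif mode == "concat":
        totals = np.empty(len(candidate_trees))
        site_rows = []
        for i, tree in enumerate(candidate_trees):
            if policy.is_trivial:
                fit = optimize_fit(tree, supermatrix, spec, tol=tol,
                                   param_maxiter=param_maxiter)
                totals[i] = fit.loglik
                if keep_site_matrix:
                    site_rows.append(per_site_log_likelihoods(fit, supermatrix))
            else:
                cfit = fit_codon_partitioned(tree, supermatrix, spec, policy,
                                             tol=tol,
                                             param_maxiter=param_maxiter)
                totals[i] = cfit.loglik
                if keep_site_matrix:
                    site_rows.append(cfit.per_site_loglik(supermatrix))
        best = int(np.argmax(totals))
        site_m = np.vstack(site_rows) if site_rows else None
        scheme_mode = (PartitionMode.CONCATENATED if policy.is_trivial
                       else PartitionMode.BY_CODON_POSITION)
        scheme = PartitionScheme.for_alignment(supermatrix, scheme_mode)
        k_tot, k_per = count_free_parameters(spec, n_taxa, scheme, policy)
        n_per = scheme.sizes()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SupermatrixCell(
        spec=spec, policy=policy, mode=mode, total_logliks=np.asarray(totals),
        best_index=best, loglik=float(np.max(totals)), k_total=k_tot,
        k_per_partition=k_per, n_per_partition=n_per,
        site_loglik_matrix=site_m,
        label=f"{spec.label}+{policy.label}/{mode}")


_POLICY_PREDECESSORS = {
    "rates": ["shared"],
    "rates+freqs": ["rates"],
    "rates+exch": ["rates"],
    "rates+freqs+exch": ["rates+freqs", "rates+exch"],
    "separate": ["rates+freqs+exch"],
}


def run_supermatrix_ladder(candidate_trees: Sequence[Tree],
                           supermatrix: PatternAlignment,
                           genes: Sequence[PatternAlignment],
                           cells: Sequence[Tuple[ModelSpec, SharingPolicy, str]],
                           *, rell_samples: int = 1000, seed=None,
                           tol: float = 1e-4, param_maxiter: int = 30
                           ) -> Tuple[pd.DataFrame, List[SupermatrixCell],
                                      Optional[RellResult]]:
    """Score a ladder of cells, build the comparison table, RELL the best.

    LRT p-values are computed against each cell's nested predecessor: the
    previous policy rung under the same (model, mode), and additionally the
    concatenated counterpart for a by-gene cell.
    """
    results: List[SupermatrixCell] = []
    for spec, policy, mode in cells:
        results.append(score_candidates(
            candidate_trees, supermatrix, genes, spec, policy, mode,
            tol=tol, param_maxiter=param_maxiter))

    by_key = {(c.spec.label, c.policy.label, c.mode): c for c in results}
    rows = []
    for c in results:
        p_val = None
        preds = []
        for pol in _POLICY_PREDECESSORS.get(c.policy.label, []):
            preds.append((c.spec.label, pol, c.mode))
        if c.mode == "by-gene":
            preds.append((c.spec.label, c.policy.label, "concat"))
        if not c.spec.gamma:
            pass
        else:
            nogamma = c.spec.label.replace("+G", "")
            preds.append((nogamma, c.policy.label, c.mode))
        ps = []
        for key in preds:
            nested = by_key.get(key)
            if nested is None:
                continue
            df = c.k_total - nested.k_total
            if df >= 1 and c.loglik >= nested.loglik - 1e-3:
                _, p = likelihood_ratio_test(
                    min(nested.loglik, c.loglik), c.loglik, df)
                ps.append(p)
        if ps:
            p_val = max(ps)
        rows.append(ModelComparisonRow(
            model=c.spec.label + "+" + c.policy.label, mode=c.mode,
            ml_tree=f"T{c.best_index + 1}", loglik=c.loglik, k=c.k_total,
            aicc=c.aicc, bic=c.bic, lrt_p=p_val))

    from .selection import build_comparison_table
    table = build_comparison_table(rows)
    best_cell = results[int(np.argmin([c.aicc for c in results]))]
    rell = None
    if best_cell.site_loglik_matrix is not None and len(candidate_trees) > 1:
        rell = rell_bootstrap(best_cell.site_loglik_matrix,
                              n_samples=rell_samples, seed=seed,
                              trees=list(candidate_trees))
    return table, results, rell
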