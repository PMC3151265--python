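"""Model and tree selection: LRTs, per-partition AICc/BIC, bootstraps,
congruence and parameter-heterogeneity summaries.

The AICc penalty is computed partition by partition and summed, so models
that add parameters per partition are charged on each partition's own
sample size; BIC mirrors that construction with K_i * ln(n_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import PatternAlignment
from .likelihood import (FittedModel, ModelSpec, optimize_fit,
                         per_site_log_likelihoods)
from .models import ModelKind, average_ts_tv_ratio
from .search import nni_hill_climb
from .trees import Tree, rf_null_distribution, robinson_foulds_normalized

__all__ = [
    "likelihood_ratio_test", "aicc_partitioned", "bic_partitioned",
    "RellResult", "rell_bootstrap", "nonparametric_bootstrap",
    "ModelTestResult", "hierarchical_gene_model_test",
    "CongruenceSummary", "congruence_summary",
    "parameter_heterogeneity_summary", "ModelComparisonRow",
    "build_comparison_table",
]

_NESTING_SLACK = 1e-6


def likelihood_ratio_test(loglik_nested: float, loglik_general: float,
                          df: int) -> Tuple[float, float]:
    """LRT statistic 2(l1 - l0) and its chi-square upper-tail p-value."""
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = loglik_general - loglik_nested
    if delta < -_NESTING_SLACK:
        raise ValueError(
            f"general model scored {-delta:.3g} nats below the nested model: "
            "broken nesting (optimization failure)")
    stat = max(0.0, 2.0 * delta)
    return stat, float(stats.chi2.sf(stat, df))


def aicc_partitioned(total_loglik: float, ks: Sequence[int],
                     ns: Sequence[int],
                     names: Optional[Sequence[str]] = None) -> float:
    """AICc with the small-sample penalty summed per partition.

    score = -2*l + sum_i [ 2 K_i + 2 K_i (K_i + 1) / (n_i - K_i - 1) ]
    """
    if len(ks) != len(ns):
        raise ValueError("K and n lists differ in length")
    penalty = 0.0
    for i, (k, n) in enumerate(zip(ks, ns)):
        if n <= k + 1:
            name = names[i] if names else f"partition {i + 1}"
            raise ValueError(
                f"{name}: sample size n={n} <= K+1={k + 1}; "
                "AICc small-sample penalty breaks down")
        penalty += 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return -2.0 * total_loglik + penalty


def bic_partitioned(total_loglik: float, ks: Sequence[int],
                    ns: Sequence[int]) -> float:
    """BIC with the penalty summed per partition: -2*l + sum K_i ln(n_i)."""
    if len(ks) != len(ns):
        raise ValueError("K and n lists differ in length")
    if any(n < 1 for n in ns):
        raise ValueError("every partition needs at least one site")
    return -2.0 * total_loglik + float(
        sum(k * np.log(n) for k, n in zip(ks, ns)))


# ---------------------------------------------------------------------
# Bootstraps


@dataclass
class RellResult:
    tree_support: np.ndarray
    n_samples: int
    bipartition_support: Optional[Dict[frozenset, float]] = None


def rell_bootstrap(site_loglik_matrix: np.ndarray, n_samples: int = 1000,
                   seed=None, trees: Optional[Sequence[Tree]] = None,
                   strata: Optional[Sequence[np.ndarray]] = None) -> RellResult:
    """Bootstrap over per-site log-likelihoods without re-optimization.

    Each replicate resamples sites with replacement, re-sums every candidate
    tree's log-likelihood and awards the replicate to the top tree (ties
    split fractionally).  ``strata`` optionally restricts resampling to be
    within site groups (e.g. partitions).
    """
    M = np.asarray(site_loglik_matrix, float)
    if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 1:
        raise ValueError("need a (n_trees, n_sites) matrix")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_trees, n_sites = M.shape
    rng = np.random.default_rng(seed)
    groups = [np.arange(n_sites)] if strata is None else \
        [np.asarray(s, int) for s in strata]
    support = np.zeros(n_trees)
    batch = max(1, min(n_samples, int(5e7 // max(n_sites, 1))))
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        totals = np.zeros((b, n_trees))
        for idx in groups:
            counts = rng.multinomial(len(idx), np.full(len(idx), 1.0 / len(idx)),
                                     size=b)
            totals += counts @ M[:, idx].T
        top = totals.max(axis=1, keepdims=True)
        winners = np.isclose(totals, top, rtol=0.0, atol=1e-9)
        support += (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0)
        done += b
    support /= n_samples
    bip = None
    if trees is not None:
        if len(trees) != n_trees:
            raise ValueError("tree list length != matrix rows")
        bip = {}
        for t, s in zip(trees, support):
            for split in t.bipartitions():
                bip[split] = bip.get(split, 0.0) + float(s)
    return RellResult(tree_support=support, n_samples=n_samples,
                      bipartition_support=bip)


def nonparametric_bootstrap(data: PatternAlignment, spec: ModelSpec,
                            ml_tree: Tree, n_reps: int = 100, seed=None, *,
                            tol: float = 1e-4, param_maxiter: int = 30,
                            neighbor_max_sweeps: int = 12
                            ) -> Dict[frozenset, float]:
    """Full bootstrap: resample columns, redo the NNI search per replicate.

    Returns support (fraction of replicate ML trees containing each split)
    for every internal bipartition of ``ml_tree``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref_splits = ml_tree.bipartitions()
    counts = {s: 0 for s in ref_splits}
    for _ in range(n_reps):
        idx = rng.integers(data.total_length, size=data.total_length)
        boot = data.subset_sites(idx)
        fit = nni_hill_climb(boot, spec, ml_tree, tol=tol,
                             param_maxiter=param_maxiter,
                             neighbor_max_sweeps=neighbor_max_sweeps)
        splits = fit.topology.bipartitions()
        for s in ref_splits:
            if s in splits:
                counts[s] += 1
    return {s: c / n_reps for s, c in counts.items()}


# ---------------------------------------------------------------------
# Hierarchical model choice


@dataclass
class ModelTestResult:
    best: ModelSpec
    p_jc_vs_hky: float
    p_hky_vs_rev: float
    fits: Dict[str, FittedModel]


def hierarchical_gene_model_test(data: PatternAlignment, tree: Tree, *,
                                 alpha_level: float = 0.05,
                                 n_categories: int = 6, tol: float = 1e-5,
                                 param_maxiter: int = 40) -> ModelTestResult:
    """LRT chain JC+G -> HKY+G (df 4) -> REV+G (df 4) on a fixed topology."""
    from .models import NucleotideModel
    specs = {k: ModelSpec(k, gamma=True, n_categories=n_categories)
             for k in (ModelKind.JC, ModelKind.HKY, ModelKind.REV)}
    fits = {}
    fits["JC"] = optimize_fit(tree, data, specs[ModelKind.JC], tol=tol,
                              param_maxiter=param_maxiter)
    # warm-start each more general model at the nested optimum so the
    # fitted chain is monotone by construction
    jc = fits["JC"]
    fits["HKY"] = optimize_fit(
        tree.copy() if jc.topology is None else jc.topology, data,
        specs[ModelKind.HKY], tol=tol, param_maxiter=param_maxiter,
        init_model=NucleotideModel.hky(np.full(4, 0.25), 1.0),
        init_alpha=jc.alpha, use_input_lengths=True)
    hky = fits["HKY"]
    kappa = hky.model.kappa
    fits["REV"] = optimize_fit(
        hky.topology, data, specs[ModelKind.REV], tol=tol,
        param_maxiter=param_maxiter,
        init_model=NucleotideModel.rev(
            hky.model.frequencies,
            np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])),
        init_alpha=hky.alpha, use_input_lengths=True)
    _, p1 = likelihood_ratio_test(fits["JC"].loglik, fits["HKY"].loglik, df=4)
    _, p2 = likelihood_ratio_test(fits["HKY"].loglik, fits["REV"].loglik, df=4)
    if p1 >= alpha_level:
        best = specs[ModelKind.JC]
    elif p2 >= alpha_level:
        best = specs[ModelKind.HKY]
    else:
        best = specs[ModelKind.REV]
    # if HKY is rejected against REV but JC was kept, the chain still stops
    # at the first non-significant step (hierarchical convention)
    return ModelTestResult(best=best, p_jc_vs_hky=p1, p_hky_vs_rev=p2,
                           fits=fits)


# ---------------------------------------------------------------------
# Congruence and heterogeneity


@dataclass
class CongruenceSummary:
    n_trees: int
    n_distinct: int
    mean_pairwise_rf: float
    null_mean: float
    null_sd: float
    p_value: float


def congruence_summary(gene_trees: Sequence[Tree], n_sims: int = 10000,
                       seed=None) -> CongruenceSummary:
    """Distinct-topology count, mean pairwise RF, and a random-tree null p."""
    if len(gene_trees) < 2:
        raise ValueError("need at least two gene trees")
    taxa = gene_trees[0].taxa
    for t in gene_trees[1:]:
        if t.taxa != taxa:
            raise ValueError("gene trees disagree on the taxon set")
    keys = {t.topology_key() for t in gene_trees}
    splits = [t.bipartitions() for t in gene_trees]
    n = len(gene_trees)
    denom = 2.0 * (len(taxa) - 3)
    vals = [len(splits[i] ^ splits[j]) / denom
            for i in range(n) for j in range(i + 1, n)]
    mean_rf = float(np.mean(vals))
    null = rf_null_distribution(len(taxa), n, n_sims=n_sims, seed=seed)
    p = float(np.mean(null <= mean_rf))
    return CongruenceSummary(n_trees=n, n_distinct=len(keys),
                             mean_pairwise_rf=mean_rf,
                             null_mean=float(null.mean()),
                             null_sd=float(null.std(ddof=1)) if n_sims > 1 else 0.0,
                             p_value=p)


def parameter_heterogeneity_summary(fits: Sequence[FittedModel],
                                    alignments: Sequence[PatternAlignment]
                                    ) -> Tuple[pd.DataFrame, dict]:
    """Per-gene R, alpha and GC, with 2.5/97.5 percentiles and full range."""
    if not fits:
        raise ValueError("no fits to summarize")
    if len(fits) != len(alignments):
        raise ValueError("fits and alignments differ in length")
    rows = []
    for fit, aln in zip(fits, alignments):
        rows.append({
            "gene": aln.gene_ids[0],
            "R": average_ts_tv_ratio(fit.model),
            "alpha": fit.alpha if fit.alpha is not None else np.nan,
            "gc": aln.gc_content(),
            "loglik": fit.loglik,
        })
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("R", "alpha", "gc"):
        v = df[col].to_numpy(float)
        v = v[~np.isnan(v)]
        summary[col] = {
            "p2.5": float(np.percentile(v, 2.5)),
            "p97.5": float(np.percentile(v, 97.5)),
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
        }
    return df, summary


# ---------------------------------------------------------------------
# Comparison tables


@dataclass
class ModelComparisonRow:
    model: str
    mode: str
    ml_tree: str
    loglik: float
    k: int
    aicc: float
    bic: float
    lrt_p: Optional[float] = None
    delta_aicc: float = 0.0
    delta_bic: float = 0.0


def build_comparison_table(rows: Sequence[ModelComparisonRow]) -> pd.DataFrame:
    """Attach delta columns (relative to the best AICc/BIC) and tabulate."""
    if not rows:
        raise ValueError("no comparison rows")
    best_aicc = min(r.aicc for r in rows)
    best_bic = min(r.bic for r in rows)
    recs = []
    for r in rows:
        r.delta_aicc = r.aicc - best_aicc
        r.delta_bic = r.bic - best_bic
        recs.append({
            "model": r.model, "mode": r.mode, "ml_tree": r.ml_tree,
            "loglik": r.loglik, "K": r.k, "dAICc": r.delta_aicc,
            "dBIC": r.delta_bic,
            "lrt_p": r.lrt_p if r.lrt_p is not None else np.nan,
        })
    return pd.DataFrame(recs)
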