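"""Shared fixtures and independent oracles for the test suite.

The brute-force likelihood oracle enumerates all internal-state assignments
and never touches the pruning engine's partial-likelihood machinery; the
gamma oracle integrates the density numerically.  Both exist to check the
fast implementations against slow, obviously-correct computations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

import phylopart as pp
from phylopart.models import NucleotideModel, build_generator


# ---------------------------------------------------------------------
# Brute-force pruning oracle (exhaustive internal-state enumeration)


def brute_force_loglik(tree, aln, model, gamma=None):
    """Sum over every internal-node state assignment, per rate category.

    Uses scipy.linalg.expm for transition probabilities (independent of the
    package's spectral path).  Ambiguous tip characters contribute factor 1.
    """
    from phylopart.likelihood import _Structure

    S = _Structure(tree)
    Q = build_generator(model)
    rates = gamma.category_rates if gamma is not None else np.ones(1)
    probs = gamma.category_probs if gamma is not None else np.ones(1)
    codes = aln.codes()
    row = {t: i for i, t in enumerate(aln.taxa)}
    nodes = range(len(S.children))
    internal = [i for i in nodes if S.children[i]]
    pi = model.frequencies
    total = 0.0
    for p in range(aln.n_patterns):
        site_l = 0.0
        for r, pr in zip(rates, probs):
            P = {i: expm(Q * (r * S.lengths[i]))
                 for i in nodes if i != S.root}
            lsum = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                for i, lab in S.leaf_label.items():
                    st[i] = int(codes[row[lab], p])
                val = pi[st[S.root]]
                for i in nodes:
                    if i == S.root or st[i] == 4:
                        continue
                    val *= P[i][st[S.parent[i]], st[i]]
                lsum += val
            site_l += pr * lsum
        total += aln.weights[p] * np.log(site_l)
    return float(total)


def brute_force_site_logliks(tree, aln, model, gamma=None):
    """Per original site, via the same enumeration."""
    out = np.empty(aln.total_length)
    per_pattern = np.empty(aln.n_patterns)
    for p in range(aln.n_patterns):
        sub = _single_pattern(aln, p)
        per_pattern[p] = brute_force_loglik(tree, sub, model, gamma)
    return per_pattern[aln.site_to_pattern]


def _single_pattern(aln, p):
    col = aln.patterns[:, p]
    seqs = [col[i].decode("ascii") for i in range(aln.n_taxa)]
    return pp.compress_patterns(aln.taxa, seqs)


# ---------------------------------------------------------------------
# Gamma-discretization oracle (adaptive quadrature)


def quadrature_gamma_rates(alpha, K):
    """Conditional means of Gamma(alpha, rate=alpha) on equal-probability
    bins, by adaptive numerical integration."""
    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], dist.ppf(np.arange(1, K) / K), [np.inf]])
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        num, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        rates.append(num * K)
    rates = np.array(rates)
    return rates / (rates.mean())


# ---------------------------------------------------------------------
# Random model / data helpers


def random_model(rng, kind="REV"):
    f = rng.dirichlet(np.full(4, 8.0))
    f = f / f.sum()
    if kind == "JC":
        return NucleotideModel.jc()
    if kind == "HKY":
        return NucleotideModel.hky(f, float(rng.uniform(0.5, 6.0)))
    return NucleotideModel.rev(f, rng.uniform(0.3, 3.0, size=6))


def random_tree_with_lengths(rng, n_taxa, lo=0.02, hi=0.8):
    taxa = [f"t{i}" for i in range(n_taxa)]
    t = pp.random_topology(taxa, rng=rng)
    for node in t.root.walk_postorder():
        if node is not t.root:
            node.length = float(rng.uniform(lo, hi))
    return t


def random_alignment(rng, taxa, n_sites):
    seqs = ["".join(rng.choice(list("ACGT"), size=n_sites)) for _ in taxa]
    return pp.compress_patterns(list(taxa), seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


@pytest.fixture(scope="session")
def small_sim():
    """A 6-taxon simulated HKY+G alignment reused across tests."""
    from phylopart.models import discretize_gamma
    from phylopart.simulate import simulate_alignment

    tree = pp.read_newick(
        "((A:0.12,B:0.09):0.06,((C:0.11,D:0.08):0.05,"
        "(E:0.1,F:0.13):0.07):0.04);")
    model = NucleotideModel.hky(np.array([0.3, 0.2, 0.2, 0.3]), 3.0)
    gamma = discretize_gamma(0.6, 6)
    aln = simulate_alignment(tree, model, gamma, 2000, seed=77)
    return tree, model, gamma, aln
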