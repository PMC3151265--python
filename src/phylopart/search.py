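"""Nearest-neighbor-interchange hill climbing over tree topologies."""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .alignment import PatternAlignment
from .likelihood import FittedModel, ModelSpec, optimize_fit
from .trees import Node, Tree, random_topology

__all__ = ["nni_neighbors", "nni_hill_climb"]


def _parent_map(root: Node) -> dict:
    parents = {}
    for node in root.walk_postorder():
        for c in node.children:
            parents[id(c)] = node
    return parents


def nni_neighbors(tree: Tree) -> List[Tree]:
    """All topologies one NNI away (2 per internal edge of the unrooted tree)."""
    base = tree.deroot()
    n_nodes = sum(1 for _ in base.root.walk_postorder())
    out: List[Tree] = []
    for i in range(n_nodes):
        for j in (0, 1):
            t = base.copy()
            nodes = list(t.root.walk_postorder())
            c = nodes[i]
            if c is t.root or c.is_leaf:
                continue
            p = _parent_map(t.root)[id(c)]
            others = [x for x in p.children if x is not c]
            z = others[0]
            if j >= len(c.children):
                continue
            x = c.children[j]
            # swap subtrees x and z across the internal edge (p, c)
            p.children[p.children.index(z)] = x
            c.children[j] = z
            out.append(t)
    return out


def nni_hill_climb(data: PatternAlignment, spec: ModelSpec, start: Tree, *,
                   restarts: int = 0, seed=None, tol: float = 1e-5,
                   max_sweeps: int = 200, param_maxiter: int = 40,
                   max_moves: int = 100,
                   neighbor_max_sweeps: int = 20) -> FittedModel:
    """Greedy NNI search: move to the best-improving neighbor until none.

    Deterministic given ``seed`` (which only drives restart topologies).
    The log-likelihood trace is nondecreasing by construction.
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(data.taxa)

    def fit(tree: Tree, warm: Optional[FittedModel],
            sweeps: Optional[int] = None) -> FittedModel:
        return optimize_fit(
            tree, data, spec, tol=tol,
            max_sweeps=sweeps if sweeps is not None else max_sweeps,
            param_maxiter=param_maxiter,
            init_model=warm.model if warm else None,
            init_alpha=warm.alpha if warm else None)

    def climb(tree: Tree) -> FittedModel:
        current = fit(tree, None)
        for _ in range(max_moves):
            best = None
            for nb in nni_neighbors(current.topology):
                # neighbors get a capped sweep budget; the winning move is
                # carried forward and keeps improving on later iterations
                cand = fit(nb, current, sweeps=neighbor_max_sweeps)
                if best is None or cand.loglik > best.loglik:
                    best = cand
            if best is not None and best.loglik > current.loglik + 1e-9:
                current = best
            else:
                break
        return current

    result = climb(start)
    for _ in range(restarts):
        alt = climb(random_topology(taxa, rng=rng))
        if alt.loglik > result.loglik:
            result = alt
    return result
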