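"""Leaf-labeled trees: Newick I/O, polytomy resolution, RF distance, random topologies.

Trees are stored rooted (arbitrary root) but carry unrooted semantics for
reversible-model likelihoods and for topology comparison: bipartitions and
the Robinson-Foulds distance are computed on the unrooted view.  Backbone
constraint trees may contain polytomies (nodes with three or more children);
``enumerate_resolutions`` expands every polytomy into all rooted local
binary arrangements.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Node",
    "Tree",
    "NewickError",
    "read_newick",
    "write_newick",
    "read_tree_file",
    "write_tree_file",
    "enumerate_resolutions",
    "count_resolutions",
    "double_factorial",
    "robinson_foulds_normalized",
    "random_topology",
    "rf_null_distribution",
]


class NewickError(ValueError):
    def __init__(self, message: str, position: Optional[int] = None):
        if position is not None:
            message = f"{message} (at offset {position})"
        super().__init__(message)
        self.position = position


class Node:
    __slots__ = ("label", "length", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None,
                 children: Optional[List["Node"]] = None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])

    def walk_postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.walk_postorder()
        yield self


class Tree:
    """A leaf-labeled tree with optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    # -- basic structure ----------------------------------------------

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.root.walk_postorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.root.walk_postorder()
                   if n is not self.root)

    def is_binary_unrooted(self) -> bool:
        """True if every vertex of the unrooted view has degree 1 or 3."""
        for node in self.root.walk_postorder():
            k = len(node.children)
            if node is self.root:
                if k not in (2, 3):
                    return False
            elif k not in (0, 2):
                return False
        if len(self.root.children) == 2:
            # a degree-2 root is a pass-through; both sides must be fine
            return True
        return True

    def max_polytomy(self) -> int:
        return max(len(n.children) for n in self.root.walk_postorder()
                   if n.children)

    def deroot(self) -> "Tree":
        """Suppress a degree-2 root, merging its two edges (unrooted view)."""
        t = self.copy()
        while len(t.root.children) == 2 and any(not c.is_leaf for c in t.root.children):
            a, b = t.root.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.length is not None or move.length is not None:
                move.length = (move.length or 0.0) + (keep.length or 0.0)
            keep.children.append(move)
            keep.length = None
            t.root = keep
        return t

    # -- bipartitions and comparison ----------------------------------

    def bipartitions(self) -> frozenset:
        """Nontrivial unrooted splits, each encoded as the side not
        containing the lexicographically smallest taxon."""
        all_taxa = self.taxa
        ref = min(all_taxa)
        splits = set()
        t = self.deroot()

        def collect(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(collect(c) for c in node.children))
            if node is not t.root and 1 < len(below) < len(all_taxa) - 1:
                side = below if ref not in below else all_taxa - below
                splits.add(side)
            return below

        collect(t.root)
        return frozenset(splits)

    def has_split(self, side) -> bool:
        """True if the unrooted tree contains the given bipartition side."""
        side = frozenset(side)
        if min(self.taxa) in side:
            side = self.taxa - side
        return side in self.bipartitions()

    def topology_key(self):
        """Canonical hashable key identifying the unrooted topology."""
        return (self.taxa, self.bipartitions())

    # -- newick -------------------------------------------------------

    def newick(self, lengths: bool = True, precision: int = 10,
               support: Optional[dict] = None) -> str:
        return write_newick(self, lengths=lengths, precision=precision,
                            support=support)

    def __repr__(self):
        return f"Tree({self.newick(lengths=self.has_branch_lengths())!r})"


# ---------------------------------------------------------------------
# Newick I/O


def read_newick(text: str) -> Tree:
    """Parse one Newick tree; polytomies allowed, lengths optional."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("newick must end with ';'", len(s))
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise NewickError("unbalanced parentheses", pos)
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.label = label
        elif node.is_leaf:
            raise NewickError("leaf without a label", start)
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise NewickError("malformed branch length", start) from None
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError("trailing characters after tree", pos)
    return Tree(root)


def write_newick(tree: Tree, lengths: bool = True, precision: int = 10,
                 support: Optional[dict] = None) -> str:
    """Serialize with deterministic child ordering (by smallest leaf label).

    ``support`` optionally maps bipartition frozensets (as produced by
    ``Tree.bipartitions``) to values written as internal node labels.
    """
    all_taxa = tree.taxa
    ref = min(all_taxa) if all_taxa else ""

    def fmt_len(node: Node) -> str:
        if lengths and node.length is not None:
            return f":{node.length:.{precision}g}"
        return ""

    def render(node: Node) -> Tuple[str, str, frozenset]:
        if node.is_leaf:
            return node.label, node.label + fmt_len(node), frozenset([node.label])
        parts = [render(c) for c in node.children]
        parts.sort(key=lambda p: p[0])
        key = parts[0][0]
        below = frozenset().union(*(p[2] for p in parts))
        label = node.label or ""
        if support is not None and 1 < len(below) < len(all_taxa) - 1:
            side = below if ref not in below else all_taxa - below
            if side in support:
                label = f"{support[side]:.3g}" if isinstance(support[side], float) \
                    else str(support[side])
        body = "(" + ",".join(p[1] for p in parts) + ")" + label + fmt_len(node)
        return key, body, below

    return render(tree.root)[1] + ";"


def read_tree_file(path) -> List[Tree]:
    """One Newick tree per (non-empty) line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_newick(line))
    return trees


def write_tree_file(path, trees: Iterable[Tree], lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, lengths=lengths) + "\n")


# ---------------------------------------------------------------------
# Polytomy resolution


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def count_resolutions(backbone: Tree) -> int:
    """Number of binary trees produced by resolving every polytomy."""
    total = 1
    for node in backbone.root.walk_postorder():
        k = len(node.children)
        if k >= 3:
            total *= double_factorial(2 * k - 3)
    return total


def _rooted_shapes(units: Sequence[int]) -> List:
    """All rooted binary shapes over the given units (nested 2-tuples).

    Generated by sequential insertion, which yields each of the
    (2k-3)!! shapes exactly once.
    """
    shapes: List = [units[0]]
    for u in units[1:]:
        nxt = []
        for shape in shapes:
            for variant in _insert_everywhere(shape, u):
                nxt.append(variant)
        shapes = nxt
    return shapes


def _insert_everywhere(shape, u) -> Iterator:
    yield (shape, u)  # above the current root
    if isinstance(shape, tuple):
        a, b = shape
        for va in _insert_everywhere(a, u):
            yield (va, b)
        for vb in _insert_everywhere(b, u):
            yield (a, vb)


def enumerate_resolutions(backbone: Tree, cap: int = 10 ** 6) -> List[Tree]:
    """All binary resolutions of a (possibly multifurcating) backbone.

    Each node with k >= 3 children is expanded into all (2k-3)!! rooted
    local arrangements of its child subtrees; new internal edges get no
    branch length.  Enumeration order is deterministic.
    """
    n = count_resolutions(backbone)
    if n > cap:
        raise ValueError(
            f"resolution count {n} exceeds cap {cap}; constrain the backbone")

    def resolve(node: Node) -> List[Node]:
        child_options = [resolve(c) for c in node.children]
        if node.is_leaf:
            return [Node(node.label, node.length)]
        out = []
        k = len(node.children)
        if k <= 2:
            for combo in itertools.product(*child_options):
                out.append(Node(node.label, node.length, list(combo)))
            return out
        shapes = _rooted_shapes(list(range(k)))
        for combo in itertools.product(*child_options):
            for shape in shapes:
                def build(sh) -> Node:
                    if isinstance(sh, tuple):
                        return Node(None, None, [build(sh[0]), build(sh[1])])
                    return combo[sh].copy()
                built = build(shape)
                top = Node(node.label, node.length, built.children if isinstance(shape, tuple) else [built])
                out.append(top)
        return out

    return [Tree(r) for r in resolve(backbone.root)]


# ---------------------------------------------------------------------
# Robinson-Foulds


def robinson_foulds_normalized(t1: Tree, t2: Tree) -> float:
    """Symmetric-difference RF distance normalized by 2(n-3)."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees must share an identical leaf set")
    n = t1.n_leaves()
    if n < 4:
        return 0.0
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2) / (2.0 * (n - 3))


# ---------------------------------------------------------------------
# Random topologies and the RF null


def random_topology(taxa: Sequence[str], seed=None,
                    rng: Optional[np.random.Generator] = None) -> Tree:
    """Uniform random unrooted binary topology via sequential addition.

    Each new leaf is attached to a uniformly chosen existing branch, which
    gives every labeled topology probability 1/(2n-5)!!.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = Node(None, None, [Node(t) for t in taxa[:3]])
    edges: List[Tuple[Node, int]] = [(root, i) for i in range(3)]
    for label in taxa[3:]:
        parent, idx = edges[int(rng.integers(len(edges)))]
        old = parent.children[idx]
        mid = Node(None, None, [old, Node(label)])
        parent.children[idx] = mid
        # the slot (parent, idx) now denotes the edge above `mid`
        edges.append((mid, 0))
        edges.append((mid, 1))
    return Tree(root)


def rf_null_distribution(n_taxa: int, n_trees: int, n_sims: int = 10000,
                         seed=None) -> np.ndarray:
    """Null samples of the mean pairwise normalized RF among random trees."""
    if n_trees < 2:
        raise ValueError("need at least 2 trees")
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    out = np.empty(n_sims)
    for s in range(n_sims):
        trees = [random_topology(taxa, rng=rng) for _ in range(n_trees)]
        splits = [t.bipartitions() for t in trees]
        denom = 2.0 * (n_taxa - 3)
        tot = 0.0
        cnt = 0
        for i in range(n_trees):
            for j in range(i + 1, n_trees):
                tot += len(splits[i] ^ splits[j]) / denom
                cnt += 1
        out[s] = tot / cnt
    return out


def rf_null_pvalue(observed_mean: float, null_samples: np.ndarray) -> float:
    """Fraction of null simulations with mean pairwise RF <= observed."""
    null_samples = np.asarray(null_samples, float)
    return float(np.mean(null_samples <= observed_mean))
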