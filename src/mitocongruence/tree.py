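"""Unrooted phylogenetic trees: construction, rearrangement, comparison.

Trees are stored rooted at a trifurcating internal node, the standard
serialization convention for unrooted binary topologies.  All leaf
nodes carry unique labels; branch lengths are expected substitutions
per site.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import dendropy
import numpy as np


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length  # length of the edge to the parent
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted binary tree held with a trifurcating root.

    Invariants: the root has 3 children (for >= 4 leaves), every other
    internal node has exactly 2, leaf labels are unique, and the edge
    count is ``2n - 3``.
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n is not self.root]

    def internal_edges(self) -> list[Node]:
        """Edges whose child endpoint is internal (NNI-eligible)."""
        return [n for n in self.edges() if not n.is_leaf()]

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add(_copy(c))
            return new

        return PhyloTree(_copy(self.root))

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 17) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                label = _quote_label(node.name)
                return f"{label}:{node.length:.{precision}g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner});"
            return f"({inner}):{node.length:.{precision}g}"

        return fmt(self.root)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        def _conv(dnode) -> Node:
            if dnode.is_leaf():
                if dnode.taxon is None or dnode.taxon.label is None:
                    raise ValueError("unlabeled leaf in input tree")
                node = Node(dnode.taxon.label, dnode.edge.length or 0.0)
            else:
                node = Node(None, dnode.edge.length or 0.0)
                for c in dnode.child_nodes():
                    node.add(_conv(c))
            return node

        root = _conv(dtree.seed_node)
        tree = cls(root)
        tree._suppress_bifurcating_root()
        labels = tree.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        return tree

    def to_dendropy(
        self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    def _suppress_bifurcating_root(self) -> None:
        """Convert a rooted (bifurcating) representation to trifurcating."""
        root = self.root
        if len(root.children) != 2:
            return
        a, b = root.children
        # merge the root edge into one child; prefer an internal child
        keep, fold = (a, b) if not a.is_leaf() else (b, a)
        if keep.is_leaf():
            raise ValueError("tree must have at least 4 leaves")
        fold.length += keep.length
        new_root = Node(None, 0.0)
        for c in keep.children:
            new_root.add(c)
        new_root.add(fold)
        self.root = new_root

    # ------------------------------------------------------------------
    # topology comparison
    # ------------------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the leaf set not containing
        a fixed reference taxon (so representation is canonical)."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        below: dict[int, frozenset] = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.name])
                continue
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            if node is self.root:
                continue
            if len(s) < 2 or len(all_leaves - s) < 2:
                continue
            out.add(s if ref not in s else all_leaves - s)
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            raise ValueError("trees have different leaf sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def scale_lengths(self, factor: float) -> None:
        for n in self.edges():
            n.length *= factor


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ():;,[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# random topologies
# ----------------------------------------------------------------------
def random_tree(
    labels: Sequence[str], seed: int, branch_length: float = 1.0
) -> PhyloTree:
    """Uniform random unrooted binary topology by sequential addition.

    Each leaf after the third is attached to an edge chosen uniformly
    among the current edges, which yields the uniform distribution over
    unrooted binary topologies.
    """
    labels = list(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    rng = np.random.default_rng(seed)
    root = Node(None)
    for lab in labels[:3]:
        root.add(Node(lab, branch_length))
    tree = PhyloTree(root)
    for lab in labels[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        _attach_on_edge(target, Node(lab, branch_length), branch_length)
    return tree


def _attach_on_edge(edge_child: Node, subtree_root: Node, stem: float) -> None:
    """Split the edge above ``edge_child`` and attach ``subtree_root``."""
    parent = edge_child.parent
    mid = Node(None, edge_child.length / 2.0)
    parent.children[parent.children.index(edge_child)] = mid
    mid.parent = parent
    edge_child.length = edge_child.length / 2.0
    mid.add(edge_child)
    subtree_root.length = stem
    mid.add(subtree_root)


def sample_species_tree(
    n_taxa: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
    median_path: float = 0.5,
) -> PhyloTree:
    """Yule (pure-birth) species tree, rescaled for realistic divergence.

    Branch lengths are rescaled so the median tip-to-tip path length is
    ``median_path`` expected substitutions per site, which gives
    informative but unsaturated alignments at mitochondrial rates.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")
    rng = np.random.default_rng(seed)
    # Yule process: iteratively split a uniformly chosen extant lineage;
    # waiting times exponential with rate = number of lineages.
    root = Node(None)
    a, b = Node(None), Node(None)
    root.add(a)
    root.add(b)
    tips = [a, b]
    while len(tips) < n_taxa:
        dt = rng.exponential(1.0 / len(tips))
        for t in tips:
            t.length += dt
        i = rng.integers(len(tips))
        parent = tips.pop(i)
        c1, c2 = Node(None), Node(None)
        parent.add(c1)
        parent.add(c2)
        tips.extend([c1, c2])
    dt = rng.exponential(1.0 / len(tips))
    for t in tips:
        t.length += dt
    order = rng.permutation(n_taxa)
    for t, k in zip(tips, order):
        t.name = labels[k]
    tree = PhyloTree(root)
    tree._suppress_bifurcating_root()
    # rescale to target median tip-to-tip distance
    d = _median_tip_distance(tree)
    if d > 0:
        tree.scale_lengths(median_path / d)
    for e in tree.edges():
        e.length = max(e.length, 1e-6)
    return tree


def _median_tip_distance(tree: PhyloTree) -> float:
    leaves = tree.leaves()
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        depth[id(node)] = depth[id(node.parent)] + node.length
    # path through root is an upper bound; with a trifurcating root the
    # exact path needs lowest common ancestors
    anc: dict[int, list] = {}
    for leaf in leaves:
        chain = []
        n = leaf
        while n is not None:
            chain.append(n)
            n = n.parent
        anc[id(leaf)] = chain
    dists = []
    for i, u in enumerate(leaves):
        su = {id(x) for x in anc[id(u)]}
        for v in leaves[i + 1 :]:
            lca = next(x for x in anc[id(v)] if id(x) in su)
            dists.append(
                depth[id(u)] + depth[id(v)] - 2 * depth[id(lca)]
            )
    return float(np.median(dists))


# ----------------------------------------------------------------------
# rearrangements
# ----------------------------------------------------------------------
def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All 2(n-3) nearest-neighbor-interchange neighbors.

    For each internal edge (parent p, child c) the two neighbors swap
    one child of c with a fixed sibling subtree on the p side; the third
    rearrangement about the edge is the identity.
    """
    out = []
    edges = tree.internal_edges()
    for idx in range(len(edges)):
        for which in (0, 1):
            out.append(_apply_nni(tree, idx, which))
    return out


def nni_move(
    tree: PhyloTree, edge_index: int, which: int
) -> tuple[PhyloTree, Node]:
    """NNI on a copy; returns the copy and the rearranged edge's child."""
    new = tree.copy()
    edges = new.internal_edges()
    c = edges[edge_index]
    p = c.parent
    sib = next(x for x in p.children if x is not c)
    moved = c.children[which]
    c.children[which] = sib
    sib.parent = c
    p.children[p.children.index(sib)] = moved
    moved.parent = p
    return new, c


def _apply_nni(tree: PhyloTree, edge_index: int, which: int) -> PhyloTree:
    return nni_move(tree, edge_index, which)[0]


def spr_neighbors_random(
    tree: PhyloTree, rng: np.random.Generator
) -> PhyloTree:
    """One random subtree-prune-and-regraft move.

    Falls back to a random NNI when no valid non-trivial regraft edge
    exists (possible only on very small trees).
    """
    for _ in range(30):
        new = tree.copy()
        edges = new.edges()
        prune = edges[rng.integers(len(edges))]
        # detach prune; suppress the degree-2 node left behind
        candidate = _spr_detach_regraft(new, prune, rng)
        if candidate is not None and candidate.n_leaves() == tree.n_leaves():
            return candidate
    # fallback: NNI
    n_int = len(tree.internal_edges())
    return _apply_nni(tree, int(rng.integers(n_int)), int(rng.integers(2)))


def _spr_detach_regraft(
    tree: PhyloTree, prune: Node, rng: np.random.Generator
) -> Optional[PhyloTree]:
    p = prune.parent
    p.children.remove(prune)
    prune.parent = None
    # suppress degree-2 node
    removed_ok = True
    if p is tree.root:
        if len(p.children) == 2:
            a, b = p.children
            keep, fold = (a, b) if not a.is_leaf() else (b, a)
            if keep.is_leaf():
                removed_ok = False
            else:
                fold.length += keep.length
                new_root = Node(None, 0.0)
                for c in keep.children:
                    new_root.add(c)
                new_root.add(fold)
                tree.root = new_root
    else:
        if len(p.children) == 1:
            only = p.children[0]
            only.length += p.length
            gp = p.parent
            gp.children[gp.children.index(p)] = only
            only.parent = gp
    if not removed_ok:
        return None
    # regraft on a random edge not inside the pruned subtree
    in_sub = {id(x) for x in _subtree_nodes(prune)}
    targets = [e for e in tree.edges() if id(e) not in in_sub]
    if not targets:
        return None
    target = targets[rng.integers(len(targets))]
    _attach_on_edge(target, prune, max(prune.length, 1e-6))
    return tree


def _subtree_nodes(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def perturb_tree(
    tree: PhyloTree, k_moves: int, move_kind: str = "NNI", seed: int = 0
) -> PhyloTree:
    """Apply ``k_moves`` random topology moves (NNI or SPR)."""
    if k_moves < 0:
        raise ValueError("k_moves must be >= 0")
    if move_kind not in ("NNI", "SPR"):
        raise ValueError(f"unknown move kind {move_kind!r}")
    rng = np.random.default_rng(seed)
    current = tree.copy()
    for _ in range(k_moves):
        if move_kind == "NNI":
            n_int = len(current.internal_edges())
            current = _apply_nni(
                current, int(rng.integers(n_int)), int(rng.integers(2))
            )
        else:
            current = spr_neighbors_random(current, rng)
    return current
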