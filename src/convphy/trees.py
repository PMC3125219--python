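"""Minimal phylogenetic tree container plus neighbor joining.

The container is deliberately small: named leaves, branch lengths, optional
node labels, Newick round-trip (via dendropy), bipartitions, and a flat
array view used by the likelihood engine.  Neighbor joining is implemented
directly on the distance matrix because the bootscan stage calls it tens of
thousands of times on <=10 taxa, where per-call overhead dominates; tests
cross-check it against scikit-bio's implementation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import dendropy
import numpy as np


class Node:
    __slots__ = ("name", "length", "children", "parent", "label", "age")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length  # branch length of edge above this node
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label: str | None = None  # e.g. bootstrap count
        self.age: float | None = None  # used by clock models

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted representation; unrooted trees carry a trifurcating root."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.label, m.age = n.label, n.age
            for c in n.children:
                m.add(rec(c))
            return m

        return Tree(rec(self.root))

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    # -- newick ---------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def rec(dn) -> Node:
            n = Node(
                dn.taxon.label.replace(" ", "_") if dn.taxon else None,
                dn.edge.length,
            )
            if dn.label and not dn.taxon:
                n.label = dn.label
            for dc in dn.child_nodes():
                n.add(rec(dc))
            return n

        return cls(rec(dt.seed_node))

    def to_newick(self, labels: bool = True) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if labels and n.label is not None:
                    s += str(n.label)
            if n.length is not None and n.parent is not None:
                s += f":{n.length:.10g}"
            return s

        return rec(self.root) + ";"

    # -- bipartitions ----------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits as the smaller/canonical leaf-name side."""
        all_leaves = frozenset(self.leaf_names)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
                if n is not self.root:
                    side = below[id(n)]
                    if 1 < len(side) < len(all_leaves) - 1:
                        other = all_leaves - side
                        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    # -- array view for likelihood ---------------------------------------
    def to_arrays(self, leaf_order: Sequence[str]) -> "TreeArrays":
        return TreeArrays.from_tree(self, leaf_order)


@dataclass
class TreeArrays:
    """Flat, index-based view: leaves first (in ``leaf_order``), root last."""

    n_leaves: int
    parent: np.ndarray  # parent index per node (-1 for root)
    children: list[list[int]]
    lengths: np.ndarray  # branch length above each node (root entry unused)
    postorder_internal: list[int]
    leaf_order: list[str]
    nodes: list[Node] = field(default_factory=list, repr=False)

    @classmethod
    def from_tree(cls, tree: Tree, leaf_order: Sequence[str]) -> "TreeArrays":
        leaves = {n.name: n for n in tree.leaves()}
        if set(leaves) != set(leaf_order):
            raise ValueError(
                f"tree leaves {sorted(leaves)} do not match ids {sorted(leaf_order)}"
            )
        order: list[Node] = [leaves[name] for name in leaf_order]
        internal = [n for n in tree.postorder() if not n.is_leaf]
        order += internal  # postorder => root last
        index = {id(n): k for k, n in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for k, node in enumerate(order):
            lengths[k] = node.length or 0.0
            if node.parent is not None:
                parent[k] = index[id(node.parent)]
            children[k] = [index[id(c)] for c in node.children]
        return cls(
            n_leaves=len(leaf_order),
            parent=parent,
            children=children,
            lengths=lengths,
            postorder_internal=[index[id(n)] for n in internal],
            leaf_order=list(leaf_order),
            nodes=order,
        )

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.postorder_internal[-1]

    def edge_nodes(self) -> np.ndarray:
        """Indices of nodes that have an edge above them (all but root)."""
        return np.array([k for k in range(self.n_nodes) if k != self.root])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(ids: Sequence[str], dmat: np.ndarray) -> Tree:
    """Saitou & Nei neighbor joining.

    Recovers the generating tree exactly (topology and branch lengths) on an
    additive matrix.  Negative branch-length estimates are clamped to zero.
    Two taxa give a single edge, three a star; the returned tree is unrooted
    (trifurcating root) for >=3 taxa.
    """
    d = np.asarray(dmat, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries (saturated pairs?)")

    nodes: list[Node] = [Node(i) for i in ids]
    if n == 1:
        return Tree(nodes[0])
    if n == 2:
        root = Node()
        a, b = nodes
        a.length, b.length = d[0, 1] / 2, d[0, 1] / 2
        root.add(a)
        root.add(b)
        return Tree(root)

    active = list(range(n))
    D = d.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = divmod(int(np.argmin(q)), m)
        if i_ > j_:
            i_, j_ = j_, i_
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node()
        nodes[gi].length, nodes[gj].length = li, lj
        new.add(nodes[gi])
        new.add(nodes[gj])
        # distances of new node to remaining
        dnew = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, dnew[None, :]])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        g_new = len(nodes) - 1
        active = [g for g in active if g not in (gi, gj)] + [g_new]

    # join the final three on a trifurcating root
    a, b, c = active
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for g, l in ((a, la), (b, lb), (c, lc)):
        nodes[g].length = max(l, 0.0)
        root.add(nodes[g])
    return Tree(root)


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_len: float = 0.1, max_len: float = 2.0
) -> tuple[Tree, list[str], np.ndarray]:
    """Random binary tree with positive branch lengths and its (additive)
    leaf-to-leaf distance matrix.  Used by property tests and simulators."""
    names = [f"t{k}" for k in range(n_taxa)]
    subtrees = [Node(nm) for nm in names]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        parent = Node()
        parent.add(a)
        parent.add(b)
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [parent]
    root = Node()
    for s in subtrees:
        s.length = float(rng.uniform(min_len, max_len))
        root.add(s)
    tree = Tree(root)
    # path distances
    dist = tree_distance_matrix(tree, names)
    return tree, names, dist


def tree_distance_matrix(tree: Tree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``ids``."""
    arr = tree.to_arrays(ids)
    n = arr.n_leaves
    # depth of every node from root, then d(u,v) = depth(u)+depth(v)-2 depth(lca)
    depth = np.zeros(arr.n_nodes)
    for k in reversed(range(arr.n_nodes)):  # root last in postorder ordering
        pass
    # compute via preorder using parent pointers
    orderd = list(arr.postorder_internal)[::-1]
    depth[arr.root] = 0.0
    stack = [arr.root]
    while stack:
        p = stack.pop()
        for c in arr.children[p]:
            depth[c] = depth[p] + arr.lengths[c]
            stack.append(c)
    # ancestors sets for lca (n small)
    anc: list[list[int]] = []
    for leaf in range(n):
        chain = []
        k = leaf
        while k != -1:
            chain.append(k)
            k = arr.parent[k]
        anc.append(chain)
    d = np.zeros((n, n))
    for i in range(n):
        seti = {k: pos for pos, k in enumerate(anc[i])}
        for j in range(i + 1, n):
            lca = next(k for k in anc[j] if k in seti)
            d[i, j] = d[j, i] = depth[i] + depth[j] - 2 * depth[lca]
    return d
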