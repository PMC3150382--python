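"""Binary dendrogram model: construction, traversal, flipping, Newick I/O.

A dendrogram is a rooted strictly binary merge tree: n labelled leaves at
height 0 and n-1 internal nodes, each carrying an absolute merge height and
an ordered (left, right) child pair.  Child order is significant — it is
the displayed left-to-right order — while the set of clades (the leaf set
under each internal node) is the clustering structure proper.  Swapping the
children of any internal node ("flipping") changes the leaf order but not
the clade set, so an n-leaf tree admits 2^(n-1) displayable orders.

Average linkage is implemented directly (Lance–Williams update) rather than
delegated to :func:`scipy.cluster.hierarchy.linkage` because reordering
experiments need a fully specified baseline: ties in merge height and the
left/right role of the merged pair follow the documented conventions below
and are reproducible across platforms.  Agreement with scipy on tie-free
inputs is exercised in the test suite.

Conventions:

* tie-break between equal-height candidate merges: the pair whose smallest
  original input index is least wins (then the smaller partner index);
* at each merge the cluster containing the lower original index becomes the
  left child;
* heights are absolute merge heights; Newick branch lengths are parent
  height minus child height, leaves sit at height 0.
"""

from __future__ import annotations

import itertools
import os
from typing import Iterator, Sequence

import numpy as np

import dendropy

from .errors import NewickParseError, ValidationError
from .matrices import DistanceMatrix


class Node:
    """A dendrogram node; leaves have ``label`` set and no children."""

    __slots__ = ("left", "right", "height", "label")

    def __init__(self, left: "Node | None" = None, right: "Node | None" = None,
                 height: float = 0.0, label: str | None = None):
        self.left = left
        self.right = right
        self.height = float(height)
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def __repr__(self) -> str:  # pragma: no cover
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node(h={self.height:g})"


class Dendrogram:
    """Rooted binary merge tree with mutable child order.

    Traversals are iterative so deep (caterpillar-shaped) trees of several
    hundred leaves do not hit the interpreter recursion limit.
    """

    def __init__(self, root: Node):
        self.root = root
        self._check()

    # -- structure ---------------------------------------------------------
    def _check(self) -> None:
        n_leaf = n_int = 0
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if node.label is None:
                    raise ValidationError("leaf without a label")
                if node.label in seen:
                    raise ValidationError(f"duplicate leaf id {node.label!r}")
                seen.add(node.label)
                n_leaf += 1
            else:
                if node.right is None:
                    raise ValidationError("internal node is not binary")
                n_int += 1
        if n_int != n_leaf - 1:
            raise ValidationError(
                f"{n_leaf} leaves require {n_leaf - 1} internal nodes, found {n_int}")
        self._leaf_ids = frozenset(seen)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_ids)

    @property
    def leaf_ids(self) -> frozenset[str]:
        return self._leaf_ids

    def postorder(self, start: Node | None = None) -> Iterator[Node]:
        stack = [(start or self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                stack.append((node.right, False))
                stack.append((node.left, False))

    def preorder(self, start: Node | None = None) -> Iterator[Node]:
        stack = [start or self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def internal_nodes(self, start: Node | None = None) -> list[Node]:
        return [nd for nd in self.preorder(start) if not nd.is_leaf]

    def depths(self) -> dict[int, int]:
        """Map ``id(node)`` -> depth (root = 0)."""
        out = {id(self.root): 0}
        for node in self.preorder():
            if not node.is_leaf:
                d = out[id(node)] + 1
                out[id(node.left)] = d
                out[id(node.right)] = d
        return out

    def leaf_lists(self, start: Node | None = None) -> dict[int, tuple[str, ...]]:
        """Map ``id(node)`` -> left-to-right leaf tuple under that node."""
        out: dict[int, tuple[str, ...]] = {}
        for node in self.postorder(start):
            if node.is_leaf:
                out[id(node)] = (node.label,)
            else:
                out[id(node)] = out[id(node.left)] + out[id(node.right)]
        return out

    def copy(self) -> "Dendrogram":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                mapping[id(node)] = Node(label=node.label)
            else:
                mapping[id(node)] = Node(mapping[id(node.left)],
                                         mapping[id(node.right)], node.height)
        return Dendrogram(mapping[id(self.root)])

    def flip(self, node: Node) -> None:
        """Swap the children of ``node`` in place."""
        if node.is_leaf:
            raise ValidationError("cannot flip a leaf")
        node.left, node.right = node.right, node.left


# -- queries ---------------------------------------------------------------

def leaf_order(tree: Dendrogram) -> list[str]:
    """Leaf ids left to right (in-order positions 1..n)."""
    return list(tree.leaf_lists()[id(tree.root)])


def flip_node(tree: Dendrogram, node: Node) -> Dendrogram:
    """Swap ``node``'s children in place and return the tree."""
    tree.flip(node)
    return tree


def clade_signature(tree: Dendrogram) -> frozenset[frozenset[str]]:
    """The set of leaf sets under each internal node.

    Invariant under any sequence of flips, so it witnesses that a
    reordering preserved the clustering structure.
    """
    lists = tree.leaf_lists()
    return frozenset(frozenset(lists[id(nd)])
                     for nd in tree.internal_nodes())


def flip_orbit_orders(tree: Dendrogram) -> set[tuple[str, ...]]:
    """All leaf orders reachable by flips (2^(n-1) subsets; small n only)."""
    nodes = tree.internal_nodes()
    if len(nodes) > 16:
        raise ValidationError("flip orbit enumeration is exponential; n too large")
    orders: set[tuple[str, ...]] = set()
    for flips in itertools.product((False, True), repeat=len(nodes)):
        for nd, f in zip(nodes, flips):
            if f:
                tree.flip(nd)
        orders.add(tuple(leaf_order(tree)))
        for nd, f in zip(nodes, flips):
            if f:
                tree.flip(nd)
    return orders


# -- average linkage -------------------------------------------------------

def cluster_average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative average linkage (UPGMA on the given dissimilarities).

    See the module docstring for the deterministic tie-break and child-order
    conventions.  O(n^3) worst case with vectorised inner steps; fine for the
    few hundred samples typical of expression studies.
    """
    n = dist.n
    if n < 2:
        raise ValidationError("need at least 2 objects to cluster")
    d = dist.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    nodes: list[Node] = [Node(label=lab) for lab in dist.labels]
    rep = np.arange(n)      # smallest original index in each slot's cluster
    size = np.ones(n)

    for _ in range(n - 1):
        sub = np.where(active[:, None] & active[None, :], d, np.inf)
        h = sub.min()
        ties = np.argwhere(sub == h)
        # canonical pair: minimise (smaller rep, larger rep)
        best = min(((min(rep[i], rep[j]), max(rep[i], rep[j]), i, j)
                    for i, j in ties if i < j))
        i, j = best[2], best[3]
        if rep[j] < rep[i]:
            i, j = j, i  # slot i holds the lower original index -> left child
        parent = Node(nodes[i], nodes[j], h)
        # Lance-Williams average update into slot i
        w = (size[i] * d[i] + size[j] * d[j]) / (size[i] + size[j])
        d[i] = w
        d[:, i] = w
        d[i, i] = np.inf
        size[i] += size[j]
        rep[i] = min(rep[i], rep[j])
        active[j] = False
        nodes[i] = parent

    return Dendrogram(nodes[np.flatnonzero(active)[0]])


# -- merge tables ----------------------------------------------------------

def linkage_to_tree(merge_table: Sequence[tuple[str, str, float]],
                    leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Build a dendrogram from a 3-column merge table.

    Each row ``(id_a, id_b, height)`` merges the current cluster containing
    leaf ``id_a`` (left child) with the one containing ``id_b`` (right
    child).  When ``leaf_ids`` is given, ids outside it are rejected;
    otherwise the leaf set is inferred from the table.
    """
    rows = [(str(a), str(b), float(h)) for a, b, h in merge_table]
    if leaf_ids is None:
        leaves = sorted({x for a, b, _ in rows for x in (a, b)})
    else:
        leaves = list(leaf_ids)
        known = set(leaves)
        for a, b, _ in rows:
            for x in (a, b):
                if x not in known:
                    raise ValidationError(f"merge table references unknown id {x!r}")
    if len(rows) != len(leaves) - 1:
        raise ValidationError(
            f"{len(leaves)} leaves need {len(leaves) - 1} merges, table has {len(rows)}")
    cluster_of = {lab: lab for lab in leaves}   # leaf id -> cluster key (its rep leaf)
    members: dict[str, list[str]] = {lab: [lab] for lab in leaves}
    node_of: dict[str, Node] = {lab: Node(label=lab) for lab in leaves}
    for a, b, h in rows:
        ka, kb = cluster_of[a], cluster_of[b]
        if ka == kb:
            raise ValidationError(
                f"merge ({a!r}, {b!r}) joins a cluster with itself")
        parent = Node(node_of[ka], node_of[kb], h)
        merged = members[ka] + members[kb]
        for x in members[kb]:
            cluster_of[x] = ka
        members[ka] = merged
        node_of[ka] = parent
        del members[kb], node_of[kb]
    if len(node_of) != 1:
        raise ValidationError("merge table does not agglomerate to a single cluster")
    return Dendrogram(next(iter(node_of.values())))


def tree_to_linkage(tree: Dendrogram) -> list[tuple[str, str, float]]:
    """Merge table for ``tree``: children before parents, representative id =
    leftmost leaf of each child.  Round-trips through :func:`linkage_to_tree`."""
    lists = tree.leaf_lists()
    rows = []
    for node in tree.postorder():
        if not node.is_leaf:
            rows.append((lists[id(node.left)][0], lists[id(node.right)][0],
                         node.height))
    return rows


def read_merge_table(path: str | os.PathLike) -> list[tuple[str, str, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                rows.append((parts[0], parts[1], float(parts[2])))
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: bad height {parts[2]!r}") from None
    return rows


def write_merge_table(rows: Sequence[tuple[str, str, float]],
                      path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b, h in rows:
            fh.write(f"{a}\t{b}\t{h!r}\n")


# -- Newick ----------------------------------------------------------------

_NEWICK_RESERVED = set("()[]{}:;,='\" \t\n")


def _quote(label: str) -> str:
    if _NEWICK_RESERVED & set(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Dendrogram) -> str:
    """Newick text; child order in the file IS the displayed order.

    Branch lengths are parent height minus child height (leaves at 0);
    heights survive a round trip exactly (shortest round-trip float form).
    """
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            parts[id(node)] = _quote(node.label)
        else:
            seg = []
            for child in (node.left, node.right):
                bl = node.height - child.height
                seg.append(f"{parts.pop(id(child))}:{bl!r}")
            parts[id(node)] = f"({seg[0]},{seg[1]})"
    return parts[id(tree.root)] + ";"


def read_newick(text: str) -> Dendrogram:
    """Parse Newick into a dendrogram, preserving child order.

    Only strictly binary trees are accepted.  Heights are reconstructed
    bottom-up from branch lengths with leaves at height 0.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from None
    conv: dict[int, Node] = {}
    height: dict[int, float] = {}
    for dnode in dtree.postorder_node_iter():
        children = dnode.child_nodes()
        if not children:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise NewickParseError("leaf without a label")
            conv[id(dnode)] = Node(label=str(label))
            height[id(dnode)] = 0.0
        elif len(children) == 2:
            hs = [height[id(c)] + (c.edge.length or 0.0) for c in children]
            conv[id(dnode)] = Node(conv[id(children[0])], conv[id(children[1])],
                                   max(hs))
            height[id(dnode)] = max(hs)
        else:
            raise NewickParseError(
                f"non-binary node with {len(children)} children; "
                "only strictly binary dendrograms are supported")
    return Dendrogram(conv[id(dtree.seed_node)])


def read_newick_file(path: str | os.PathLike) -> Dendrogram:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: Dendrogram, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
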