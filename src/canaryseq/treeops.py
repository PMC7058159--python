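"""Unrooted phylogenetic trees: Newick I/O, pruning, and comparison.

All comparisons in the canary pipeline are topological and unrooted: two
trees are "isomorphic" iff their nontrivial bipartition (split) sets are
identical, i.e. Robinson-Foulds distance zero, and a leaf's "position" is
the unordered collection of leaf sets of the subtrees adjacent to its
attachment node. Rooted Newick input is accepted and stored unrooted (a
degree-2 root is suppressed). Branch lengths are carried for inference and
simulation but are ignored by every isomorphism/placement decision.

Newick parsing is delegated to dendropy; the canonical writer below is
deterministic (children ordered by smallest descendant label) so that
byte-identical output certifies identical topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Hashable, Iterable, Mapping

import dendropy

from canaryseq.errors import NewickError, TreeError

__all__ = [
    "Tree",
    "Placement",
    "parse_newick",
    "write_newick",
    "prune_leaves",
    "rf_distance",
    "restrict_to_shared",
    "placement",
    "same_placement",
    "is_monophyletic",
    "nontrivial_splits",
]

BranchLength = float | None


class Tree:
    """An unrooted tree over uniquely labeled leaves.

    Internally an adjacency map ``node -> {neighbor: branch_length}`` over
    integer node ids; leaves are the degree-1 nodes and carry labels.
    Internal nodes are unlabeled and never of degree 2. Instances should be
    treated as immutable; operations return new trees.
    """

    __slots__ = ("adj", "labels", "_node_of")

    def __init__(
        self,
        adj: dict[int, dict[int, BranchLength]],
        labels: dict[int, str],
    ) -> None:
        self.adj = adj
        self.labels = labels
        self._node_of = {lab: node for node, lab in labels.items()}
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable, BranchLength]],
        leaf_labels: Mapping[Hashable, str],
    ) -> "Tree":
        """Build a tree from an edge list with arbitrary hashable node keys."""
        index: dict[Hashable, int] = {}

        def nid(key: Hashable) -> int:
            if key not in index:
                index[key] = len(index)
            return index[key]

        adj: dict[int, dict[int, BranchLength]] = {}
        for a, b, length in edges:
            ia, ib = nid(a), nid(b)
            adj.setdefault(ia, {})[ib] = length
            adj.setdefault(ib, {})[ia] = length
        labels = {index[k]: lab for k, lab in leaf_labels.items() if k in index}
        return cls(adj, labels)

    def copy(self) -> "Tree":
        return Tree(
            {u: dict(nbrs) for u, nbrs in self.adj.items()}, dict(self.labels)
        )

    def _validate(self) -> None:
        if len(set(self.labels.values())) != len(self.labels):
            raise NewickError("duplicate leaf labels")
        if len(self.labels) < 3:
            raise NewickError(
                f"tree must have at least 3 leaves, got {len(self.labels)}"
            )
        for node, nbrs in self.adj.items():
            deg = len(nbrs)
            if node in self.labels:
                if deg != 1:
                    raise NewickError(
                        f"leaf {self.labels[node]!r} has degree {deg}"
                    )
            elif deg < 3:
                raise NewickError(f"internal node of degree {deg}")
        # connectivity
        seen: set[int] = set()
        stack = [next(iter(self.adj))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.adj[u])
        if seen != set(self.adj):
            raise NewickError("tree is not connected")

    # -- basic queries -------------------------------------------------

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_of(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def has_branch_lengths(self) -> bool:
        return all(
            length is not None
            for nbrs in self.adj.values()
            for length in nbrs.values()
        )

    def edges(self) -> list[tuple[int, int, BranchLength]]:
        """Undirected edge list with u < v."""
        return [
            (u, v, length)
            for u, nbrs in self.adj.items()
            for v, length in nbrs.items()
            if u < v
        ]

    def pendant_length(self, label: str) -> BranchLength:
        node = self.node_of(label)
        (length,) = self.adj[node].values()
        return length

    def preorder_edges(self, root: int) -> list[tuple[int, int, BranchLength]]:
        """(parent, child, length) triples in preorder from *root*."""
        out: list[tuple[int, int, BranchLength]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            for child, length in sorted(self.adj[node].items(), reverse=True):
                if child != parent:
                    out.append((node, child, length))
                    stack.append((child, node))
        return out

    def any_internal_node(self) -> int:
        for node in self.adj:
            if node not in self.labels:
                return node
        raise TreeError("tree has no internal node")

    def _leafset_away(self, start: int, blocked: int) -> frozenset[str]:
        """Leaf labels reachable from *start* without crossing *blocked*."""
        seen = {blocked, start}
        stack = [start]
        out = []
        while stack:
            u = stack.pop()
            if u in self.labels:
                out.append(self.labels[u])
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    # -- splits --------------------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits, each as its canonical side.

        The canonical side of a split is the side that does NOT contain the
        lexicographically smallest leaf label, so equal split sets compare
        equal across trees on the same leaf set.
        """
        anchor = min(self.leaf_set)
        root = self.node_of(anchor)
        n = self.n_leaves
        below: dict[int, frozenset[str]] = {}
        order = self.preorder_edges(root)
        for parent, child, _ in reversed(order):
            if child in self.labels:
                below[child] = frozenset((self.labels[child],))
            else:
                below[child] = frozenset().union(
                    *(below[c] for c in self.adj[child] if c != parent)
                )
        sides = {
            side
            for side in below.values()
            if 2 <= len(side) <= n - 2
        }
        return frozenset(sides)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)!r})"


@dataclass(frozen=True)
class Placement:
    """The local position of a focal leaf.

    ``neighbor_sets`` holds one leaf-label set per non-focal subtree
    attached at the focal leaf's attachment node; the sets are disjoint and
    jointly cover every leaf except the focal one.
    """

    focal_id: str
    neighbor_sets: frozenset[frozenset[str]]


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; rooted input is stored unrooted.

    Internal-node labels and support values are tolerated and dropped; a
    degree-2 root is suppressed with branch lengths summed.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    adj: dict[int, dict[int, BranchLength]] = {}
    labels: dict[int, str] = {}
    index: dict[Any, int] = {}

    def nid(dnode: Any) -> int:
        if dnode not in index:
            index[dnode] = len(index)
            adj.setdefault(index[dnode], {})
        return index[dnode]

    for dnode in dtree.preorder_node_iter():
        node = nid(dnode)
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickError("leaf without a label")
            labels[node] = dnode.taxon.label
        if dnode.parent_node is not None:
            parent = nid(dnode.parent_node)
            adj[parent][node] = dnode.edge.length
            adj[node][parent] = dnode.edge.length

    labs = list(labels.values())
    if len(set(labs)) != len(labs):
        raise NewickError("duplicate leaf labels in Newick input")
    _suppress_degree_two(adj, labels)
    return Tree(adj, labels)


def _sum_lengths(a: BranchLength, b: BranchLength) -> BranchLength:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _suppress_degree_two(
    adj: dict[int, dict[int, BranchLength]], labels: dict[int, str]
) -> None:
    """Remove unlabeled degree-2 nodes in place, summing branch lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node in labels or len(adj[node]) != 2:
                continue
            (a, la), (b, lb) = adj[node].items()
            del adj[a][node]
            del adj[b][node]
            del adj[node]
            merged = _sum_lengths(la, lb)
            adj[a][b] = merged
            adj[b][a] = merged
            changed = True


def _format_length(length: float) -> str:
    return repr(float(length))


def write_newick(tree: Tree, lengths: bool = True) -> str:
    """Canonical deterministic Newick.

    The tree is written from the internal node adjacent to the smallest
    leaf label, with children everywhere ordered by their smallest
    descendant label; re-parsing reproduces the split set exactly. Branch
    lengths are emitted with round-trip precision, or omitted entirely for
    topology-only trees (or when ``lengths=False``).
    """
    emit_lengths = lengths and tree.has_branch_lengths()
    anchor = tree.node_of(min(tree.leaf_set))
    root = next(iter(tree.adj[anchor]))

    min_below: dict[tuple[int, int], str] = {}

    def min_label(node: int, parent: int) -> str:
        key = (node, parent)
        if key not in min_below:
            if node in tree.labels:
                min_below[key] = tree.labels[node]
            else:
                min_below[key] = min(
                    min_label(c, node) for c in tree.adj[node] if c != parent
                )
        return min_below[key]

    def render(node: int, parent: int) -> str:
        length = tree.adj[node][parent]
        suffix = f":{_format_length(length)}" if emit_lengths and length is not None else ""
        if node in tree.labels:
            return tree.labels[node] + suffix
        children = sorted(
            (c for c in tree.adj[node] if c != parent),
            key=lambda c: min_label(c, node),
        )
        inner = ",".join(render(c, node) for c in children)
        return f"({inner})" + suffix

    children = sorted(tree.adj[root], key=lambda c: min_label(c, root))
    inner = ",".join(render(c, root) for c in children)
    return f"({inner});"


# ---------------------------------------------------------------------
# Topological operations
# ---------------------------------------------------------------------

def prune_leaves(tree: Tree, ids: Iterable[str]) -> Tree:
    """Remove the named leaves and return the induced suppressed subtree.

    Degree-2 nodes arising from removal are suppressed with their incident
    branch lengths summed. At least 3 leaves must remain.
    """
    to_remove = set(ids)
    unknown = to_remove - tree.leaf_set
    if unknown:
        raise TreeError(f"cannot prune unknown leaves: {sorted(unknown)}")
    if tree.n_leaves - len(to_remove) < 3:
        raise TreeError(
            f"pruning {len(to_remove)} leaves would leave fewer than 3"
        )
    work = tree.copy()
    adj, labels = work.adj, work.labels
    for label in to_remove:
        node = work._node_of[label]
        (nbr,) = adj[node]
        del adj[nbr][node]
        del adj[node]
        del labels[node]
    # remove dangling unlabeled tips created by the pruning
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node not in labels and len(adj[node]) == 1:
                (nbr,) = adj[node]
                del adj[nbr][node]
                del adj[node]
                changed = True
    _suppress_degree_two(adj, labels)
    return Tree(adj, labels)


def nontrivial_splits(tree: Tree) -> frozenset[frozenset[str]]:
    """Canonical nontrivial split set of *tree* (see :meth:`Tree.splits`)."""
    return tree.splits()


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: |symmetric difference of split sets|.

    Requires identical leaf sets; zero iff the trees are topologically
    isomorphic. Use :func:`restrict_to_shared` first for trees over
    different leaf sets.
    """
    if t1.leaf_set != t2.leaf_set:
        raise TreeError(
            "rf_distance requires identical leaf sets; restrict to the "
            "shared leaves first"
        )
    return len(t1.splits() ^ t2.splits())


def restrict_to_shared(t1: Tree, t2: Tree) -> tuple[Tree, Tree]:
    """Prune both trees down to their shared leaf set (>= 3 leaves)."""
    shared = t1.leaf_set & t2.leaf_set
    if len(shared) < 3:
        raise TreeError(
            f"only {len(shared)} shared leaves; need at least 3"
        )
    r1 = prune_leaves(t1, t1.leaf_set - shared) if t1.leaf_set != shared else t1
    r2 = prune_leaves(t2, t2.leaf_set - shared) if t2.leaf_set != shared else t2
    return r1, r2


def placement(tree: Tree, focal: str) -> Placement:
    """Position of *focal*: leaf sets of the subtrees at its attachment node."""
    node = tree.node_of(focal)
    (attach,) = tree.adj[node]
    sets = frozenset(
        tree._leafset_away(nbr, attach)
        for nbr in tree.adj[attach]
        if nbr != node
    )
    return Placement(focal_id=focal, neighbor_sets=sets)


def same_placement(t1: Tree, t2: Tree, focal: str) -> bool:
    """True iff *focal* occupies the identical local position in both trees.

    Both trees are first restricted to their shared leaf set, which must
    contain the focal leaf plus at least 3 others.
    """
    if focal not in t1.leaf_set or focal not in t2.leaf_set:
        raise TreeError(f"focal leaf {focal!r} missing from one of the trees")
    r1, r2 = restrict_to_shared(t1, t2)
    if r1.n_leaves - 1 < 3:
        raise TreeError(
            "placement comparison needs at least 3 shared leaves besides "
            f"the focal leaf; have {r1.n_leaves - 1}"
        )
    return placement(r1, focal).neighbor_sets == placement(r2, focal).neighbor_sets


def is_monophyletic(tree: Tree, group: Iterable[str]) -> bool:
    """True iff *group* (or its complement) is one side of some split.

    Singletons, the full leaf set, and sets missing a single leaf are
    monophyletic by convention (trivial splits).
    """
    members = frozenset(group)
    if not members:
        raise TreeError("monophyly of an empty group is undefined")
    unknown = members - tree.leaf_set
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    n = tree.n_leaves
    if len(members) in (1, n - 1, n):
        return True
    anchor = min(tree.leaf_set)
    target = members if anchor not in members else tree.leaf_set - members
    return target in tree.splits()
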