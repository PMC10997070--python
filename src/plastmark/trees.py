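"""Phylogenetic tree container with newick I/O and split utilities.

Trees are stored rooted for traversal purposes but are compared as
unrooted objects (via their nontrivial bipartitions) throughout the
pipeline.  Newick parsing is delegated to dendropy; serialization is a
plain recursive writer.
"""

from __future__ import annotations

import dendropy


class Node:
    __slots__ = ("name", "length", "children", "support")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        children: list["Node"] | None = None,
        support: float | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children = children if children is not None else []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.name, self.length, [c.copy() for c in self.children], self.support
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, {self.length:g}, {len(self.children)} children)"


class PhyloTree:
    """Rooted container for a (possibly conceptually unrooted) tree."""

    def __init__(self, root: Node) -> None:
        self.root = root
        names = self.tip_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip names")

    # ---------------------------------------------------------------- basics

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, visited = stack.pop()
            if visited:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def parent_map(self) -> dict[int, Node]:
        parents: dict[int, Node] = {}
        for node in self.preorder():
            for child in node.children:
                parents[id(child)] = node
        return parents

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: Node, depth: float) -> None:
            if node.is_leaf:
                depths[node.name] = depth
            for child in node.children:
                walk(child, depth + child.length)

        walk(self.root, 0.0)
        return depths

    def below_sets(self) -> dict[int, frozenset[str]]:
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        return below

    def pairwise_tip_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distances between every unordered tip pair."""
        dists: dict[tuple[str, str], float] = {}
        below: dict[int, list[tuple[str, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(node.name, 0.0)]
            else:
                kids = [
                    [(t, d + c.length) for t, d in below[id(c)]] for c in node.children
                ]
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        for t1, d1 in kids[i]:
                            for t2, d2 in kids[j]:
                                key = (t1, t2) if t1 < t2 else (t2, t1)
                                dists[key] = d1 + d2
                merged = [pair for k in kids for pair in k]
                below[id(node)] = merged
        return dists

    def mean_pairwise_distance(self) -> float:
        dists = self.pairwise_tip_distances()
        return sum(dists.values()) / len(dists)

    def scale(self, factor: float) -> "PhyloTree":
        out = self.copy()
        for node in out.postorder():
            node.length *= factor
        return out

    # ---------------------------------------------------------------- splits

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions of the unrooted tree.

        Each split is canonicalized as the frozenset of tip names on the
        side *not* containing the lexicographically smallest tip.
        """
        all_tips = frozenset(self.tip_names())
        ref = min(all_tips)
        n = len(all_tips)
        out: set[frozenset[str]] = set()
        for side in self.below_sets().values():
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return frozenset(out)

    # ---------------------------------------------------------------- newick

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = ""
        if include_support and self.root.support is not None:
            label = f"{self.root.support:g}"
        elif self.root.name:
            label = self.root.name
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def convert(dnode) -> Node:
            name = None
            support = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label is not None:
                # numeric internal labels are read as support values
                try:
                    support = float(dnode.label)
                except ValueError:
                    name = dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            return Node(
                name,
                float(length),
                [convert(c) for c in dnode.child_nodes()],
                support,
            )

        return cls(convert(dtree.seed_node))

    # ------------------------------------------------------------- rerooting

    def reroot_above(self, target: Node, offset: float | None = None) -> "PhyloTree":
        """Place a new root on the edge above ``target``.

        ``offset`` is the distance from ``target`` up to the new root
        (defaults to half the edge length).  ``target`` must belong to
        this tree and must not be the root.
        """
        return PhyloTree(_reroot(self, target, offset))

    def reroot_at_split(self, side: frozenset[str]) -> "PhyloTree":
        """Reroot on the edge inducing the given bipartition side."""
        tree = self.copy()
        all_tips = frozenset(tree.tip_names())
        below = tree.below_sets()
        for node in tree.postorder():
            if node is tree.root:
                continue
            b = below[id(node)]
            if b == side or b == all_tips - side:
                return tree.reroot_above(node)
        raise ValueError("no edge matches the requested split")

    def midpoint_root(self) -> "PhyloTree":
        """Root at the midpoint of the longest tip-to-tip path."""
        tree = self.copy()
        down: dict[int, float] = {}
        for node in tree.postorder():
            down[id(node)] = (
                0.0
                if node.is_leaf
                else max(down[id(c)] + c.length for c in node.children)
            )
        # upval[n]: farthest tip distance from n going through its parent
        upval: dict[int, float] = {id(tree.root): 0.0}
        for node in tree.preorder():
            for child in node.children:
                best_sib = max(
                    (down[id(s)] + s.length for s in node.children if s is not child),
                    default=0.0,
                )
                base = best_sib if node is tree.root else max(
                    upval[id(node)], best_sib
                )
                upval[id(child)] = base + child.length
        best: tuple[float, Node, float] | None = None
        for node in tree.postorder():
            if node is tree.root:
                continue
            x = (upval[id(node)] - down[id(node)]) / 2.0
            x = min(max(x, 0.0), node.length)
            score = max(down[id(node)] + x, upval[id(node)] - x)
            if best is None or score < best[0] - 1e-12:
                best = (score, node, x)
        assert best is not None
        _, target, x = best
        return tree.reroot_above(target, offset=x)


def _reroot(tree: PhyloTree, target: Node, offset: float | None = None) -> Node:
    parents = tree.parent_map()
    if id(target) not in parents:
        raise ValueError("cannot reroot at the root's own edge")
    path = [parents[id(target)]]
    while id(path[-1]) in parents:
        path.append(parents[id(path[-1])])
    up_lengths = [node.length for node in path]
    path[0].children.remove(target)
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
        path[i].children.append(path[i + 1])
        path[i + 1].length = up_lengths[i]
    # splice out an old root left with a single child
    if len(path) >= 2:
        old_root = path[-1]
        if len(old_root.children) == 1:
            only = old_root.children[0]
            path[-2].children.remove(old_root)
            path[-2].children.append(only)
            only.length += old_root.length
    full = target.length
    x = full / 2.0 if offset is None else min(max(offset, 0.0), full)
    target.length = x
    parent_side = path[0]
    parent_side.length = full - x
    parent_side.support = None
    new_root = Node(None, 0.0, [target, parent_side])
    # splice the parent side too if it degenerated to a single child
    if len(parent_side.children) == 1 and parent_side.name is None:
        only = parent_side.children[0]
        only.length += parent_side.length
        new_root.children[1] = only
    return new_root
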