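"""A minimal phylogenetic tree container.

Trees are unrooted in meaning but stored rooted at an arbitrary internal
node, as is conventional for Newick. Branch lengths are non-negative;
internal nodes may carry integer bootstrap supports which serialize as
internal-node labels.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

import numpy as np


class Node:
    __slots__ = ("label", "length", "support", "children")

    def __init__(self, label: str = "", length: float = 0.0,
                 support: Optional[float] = None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = list(children or [])

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal ----------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    # -- serialization ------------------------------------------------------

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if supports and node.support is not None:
                    label = str(int(round(node.support)))
                s = f"({inner}){label}"
            if lengths and not top:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root, True) + ";"

    # -- metrics ------------------------------------------------------------

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distances, labels sorted."""
        labels = self.leaf_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def walk(node: Node) -> dict[int, float]:
            # distances from every leaf under `node` up to `node`
            if node.is_leaf:
                return {index[node.label]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child in node.children:
                m = {k: v + child.length for k, v in walk(child).items()}
                child_maps.append(m)
            for a, b in itertools.combinations(child_maps, 2):
                for i, di in a.items():
                    for j, dj in b.items():
                        dist[i, j] = dist[j, i] = di + dj
            for m in child_maps:
                below.update(m)
            return below

        walk(self.root)
        return labels, dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits induced by internal edges.

        Each split is canonicalized as the side NOT containing the
        lexicographically smallest leaf, so splits compare across trees
        with the same leaf set.
        """
        all_leaves = frozenset(n.label for n in self.leaves())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def annotate_supports(self, support_of_split: dict[frozenset[str], float]) -> None:
        """Attach supports to the internal nodes whose subtree induces each split."""
        all_leaves = frozenset(n.label for n in self.leaves())
        anchor = min(all_leaves)

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                if side in support_of_split:
                    node.support = support_of_split[side]
            return below

        walk(self.root)

    def collapse_low_support(self, cutoff: float) -> "Tree":
        """Consensus view: contract internal edges with support <= cutoff
        (strict >, retained branches only). Returns a new tree."""

        def copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support,
                       [copy(c) for c in node.children])
            merged = []
            for child in new.children:
                if (not child.is_leaf and child.support is not None
                        and child.support <= cutoff):
                    for gc in child.children:
                        gc.length += 0.0  # lengths of collapsed edges are dropped
                        merged.append(gc)
                else:
                    merged.append(child)
            new.children = merged
            return new

        return Tree(copy(self.root))
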