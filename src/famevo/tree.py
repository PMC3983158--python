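"""Phylogenetic tree container, Newick serialization, splits and rerooting.

The container is deliberately small: nodes with branch lengths and optional
integer bootstrap supports on internal edges. Unrooted trees are stored
rooted at an arbitrary (usually trifurcating) node; topological comparisons
go through leaf bipartitions, which are rooting-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = ["TreeNode", "PhyloTree", "write_newick", "read_newick"]


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


class PhyloTree:
    """A tree over named leaves with branch lengths and bootstrap supports."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = root.leaf_names()
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def __len__(self) -> int:
        return len(self.leaf_names)

    # -- bipartitions ------------------------------------------------------

    def splits(self, with_support: bool = False):
        """Non-trivial leaf bipartitions, each canonicalized to the side
        not containing the lexicographically smallest leaf.

        Returns a set of frozensets, or a dict split -> support when
        ``with_support`` is true.
        """
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: dict[frozenset, Optional[float]] = {}

        def collect(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(collect(c) for c in node.children))
            side = below if ref not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                prev = out.get(side)
                if prev is None or (node.support is not None):
                    out[side] = node.support
            return below

        collect(self.root)
        return out if with_support else set(out)

    # -- rerooting ---------------------------------------------------------

    def _adjacency(self):
        """Undirected edge list with per-edge length and support."""
        nodes: list[TreeNode] = list(self.root.walk())
        idx = {id(n): i for i, n in enumerate(nodes)}
        adj: dict[int, list[tuple[int, float, Optional[float]]]] = {
            i: [] for i in range(len(nodes))
        }
        for n in nodes:
            for c in n.children:
                i, j = idx[id(n)], idx[id(c)]
                adj[i].append((j, c.length, c.support))
                adj[j].append((i, c.length, c.support))
        return nodes, adj

    def reroot_on_edge(self, child_node: TreeNode, fraction: float = 0.5) -> "PhyloTree":
        """Return a rooted copy with the root placed on the edge above
        ``child_node`` (a node of this tree), ``fraction`` of the branch
        length away from the child."""
        nodes, adj = self._adjacency()
        idx = {id(n): i for i, n in enumerate(nodes)}
        ci = idx[id(child_node)]
        parent = None
        for n in nodes:
            if child_node in n.children:
                parent = n
        if parent is None:
            raise ValueError("cannot reroot on the edge above the root")
        pi = idx[id(parent)]

        def build(i: int, exclude: int) -> TreeNode:
            src = nodes[i]
            node = TreeNode(name=src.name)
            for j, length, support in adj[i]:
                if j == exclude:
                    continue
                sub = build(j, i)
                sub.length = length
                sub.support = support
                node.children.append(sub)
            return node

        left = build(ci, pi)
        right = build(pi, ci)
        edge_len = child_node.length
        edge_sup = child_node.support
        left.length = edge_len * fraction
        right.length = edge_len * (1.0 - fraction)
        left.support = edge_sup
        right.support = edge_sup
        root = TreeNode(children=[left, right])
        return PhyloTree(root, rooted=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return _node_eq(self.root, other.root)


def _node_eq(a: TreeNode, b: TreeNode, tol: float = 1e-9) -> bool:
    if a.name != b.name or abs(a.length - b.length) > tol:
        return False
    if (a.support is None) != (b.support is None):
        return False
    if a.support is not None and abs(a.support - b.support) > tol:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(_node_eq(x, y, tol) for x, y in zip(a.children, b.children))


# ---------------------------------------------------------------------------
# Newick


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        label = node.name or ""
        return f"{label}:{node.length:g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    label = "" if node.support is None else f"{int(round(node.support))}"
    return f"({inner}){label}:{node.length:g}"


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize with branch lengths and integer bootstrap labels on
    internal nodes; returns the string and optionally writes it."""
    for node in tree.root.walk():
        if node.is_leaf and not node.name:
            raise ValueError("unnamed leaf cannot be serialized")
    if tree.root.is_leaf:
        raise ValueError("tree must have at least one internal node")
    inner = ",".join(_to_newick(c) for c in tree.root.children)
    label = "" if tree.root.support is None else f"{int(round(tree.root.support))}"
    text = f"({inner}){label};"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> PhyloTree:
    """Parse Newick (path or literal string) into a :class:`PhyloTree`.

    Internal node labels are interpreted as bootstrap supports when they
    are plain numbers.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source
        if not text.lstrip().startswith("(") and Path(text).exists():
            text = Path(text).read_text()
    dt = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
        )
        label = dnode.label
        if label is not None and not dnode.is_leaf():
            try:
                node.support = float(label)
            except ValueError:
                pass
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dt.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)
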