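"""Minimal rooted-tree structure for likelihood, parsimony and search.

Unrooted trees are represented with a trifurcating root.  Newick input
is parsed through dendropy; emission is a straightforward recursion.
"""

from __future__ import annotations

from typing import Iterator


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    # -- construction -------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    # -- traversal ----------------------------------------------------
    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "Node":
        clone = Node(self.name, self.length)
        clone.support = self.support
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    # -- newick -------------------------------------------------------
    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    @staticmethod
    def from_newick(newick: str) -> "Node":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            node = Node(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length or 0.0,
            )
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return convert(dtree.seed_node)

    # -- topology utilities -------------------------------------------
    def suppress_unifurcations(self) -> "Node":
        """Collapse degree-2 internal nodes (in place); returns self or new root."""
        root = self
        while len(root.children) == 1 and not root.is_leaf:
            child = root.children[0]
            child.parent = None
            child.length = 0.0
            root = child
        for node in list(root.postorder()):
            if node is root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        return root

    def unroot(self) -> "Node":
        """Return an equivalent tree with a trifurcating root (in place)."""
        if len(self.children) != 2:
            return self
        a, b = self.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # two-leaf tree: nothing to unroot
            return self
        fold.length += keep.length
        keep.length = 0.0
        new_root = Node(self.name)
        for c in keep.children:
            new_root.add_child(c)
        new_root.add_child(fold)
        return new_root

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted topology.

        Each split is the frozenset of leaf names on the side *not*
        containing the lexicographically smallest leaf, so splits are
        comparable across rootings.
        """
        all_names = frozenset(self.leaf_names())
        anchor = min(all_names)
        splits: set[frozenset] = set()
        for node in self.postorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_names - side
            if 1 < len(side) < len(all_names) - 1:
                splits.add(side)
        return splits

    def find(self, name: str) -> "Node":
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)


def robinson_foulds(t1: Node, t2: Node) -> int:
    s1, s2 = t1.bipartitions(), t2.bipartitions()
    return len(s1 ^ s2)
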