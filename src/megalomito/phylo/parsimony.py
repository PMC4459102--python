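"""Fitch parsimony: minimum substitution counts on a fixed topology.

State sets are bitmasks (A=1, C=2, G=4, T=8); N and gaps are fully
ambiguous.  The bottom-up pass yields the total step count; a single
top-down most-parsimonious reconstruction (ties resolved toward the
lowest base in A<C<G<T order) assigns per-branch step counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import MultipleAlignment
from .tree import Node

_FULL = np.uint8(0b1111)


@dataclass
class ParsimonyResult:
    total_steps: int
    # branches keyed by the frozenset of leaf names below them (a leaf
    # branch is keyed by the singleton set of its name)
    branch_steps: dict[frozenset, int]

    def steps_for(self, leaf_name: str) -> int:
        return self.branch_steps[frozenset([leaf_name])]


def _branch_key(node: Node) -> frozenset:
    return frozenset(node.leaf_names())


def _binarize_root(topology: Node) -> Node:
    """Root a trifurcating (unrooted) tree on its first root edge.

    Fitch's bottom-up pass is exact on binary rooted trees; rooting an
    unrooted binary tree on any edge leaves the score unchanged.
    """
    if len(topology.children) <= 2:
        return topology
    t = topology.copy()
    first = t.children[0]
    rest = Node()
    for c in t.children[1:]:
        rest.add_child(c)
    new_root = Node()
    new_root.add_child(first)
    new_root.add_child(rest)
    return new_root


def fitch_parsimony(aln: MultipleAlignment, topology: Node) -> ParsimonyResult:
    """Fitch score and per-branch substitution counts for ``topology``."""
    topology = _binarize_root(topology)
    taxa = topology.leaf_names()
    missing = set(taxa) - set(aln.ids)
    if missing:
        raise ValueError(f"taxa absent from alignment: {sorted(missing)}")

    sets: dict[int, np.ndarray] = {}
    total = 0
    for node in topology.postorder():
        if node.is_leaf:
            codes = aln.row(node.name)
            s = np.where(codes < 4, np.left_shift(1, codes.astype(np.int64)),
                         int(_FULL)).astype(np.uint8)
        else:
            s = None
            for child in node.children:
                cs = sets[id(child)]
                if s is None:
                    s = cs
                else:
                    inter = s & cs
                    empty = inter == 0
                    total += int(empty.sum())
                    s = np.where(empty, s | cs, inter)
        sets[id(node)] = s

    # top-down reconstruction: lowest set bit, parent state kept when possible
    def lowest_bit(mask: np.ndarray) -> np.ndarray:
        return (mask & (~mask + 1)).astype(np.uint8)

    states: dict[int, np.ndarray] = {id(topology): lowest_bit(sets[id(topology)])}
    branch_steps: dict[frozenset, int] = {}
    for node in topology.preorder():
        if node is topology:
            continue
        parent_state = states[id(node.parent)]
        own = sets[id(node)]
        keep = (own & parent_state) != 0
        state = np.where(keep, parent_state, lowest_bit(own))
        states[id(node)] = state.astype(np.uint8)
        branch_steps[_branch_key(node)] = int((~keep).sum())
    return ParsimonyResult(total_steps=total, branch_steps=branch_steps)
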