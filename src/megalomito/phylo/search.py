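"""Tree search: neighbor-joining start, NNI hill-climbing, bootstrap.

Maximum likelihood searches start from a log-det-distance NJ tree and
hill-climb by nearest-neighbor interchange with per-branch scalar
(Brent) branch-length optimization; maximum parsimony uses a
p-distance NJ start and the Fitch score as objective, reporting branch
"lengths" as per-branch substitution counts.  Bootstrap support is the
percentage of column-resampled replicates whose inferred tree contains
each bipartition of the point-estimate tree.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MultipleAlignment
from .likelihood import gtr_gamma_loglik
from .model import PhyloModel
from .parsimony import fitch_parsimony
from .tree import Node

_MAX_DIST = 5.0


def p_distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Pairwise proportion of differing resolved sites."""
    m = aln.matrix
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] < 4) & (m[j] < 4)
            tot = int(ok.sum())
            d[i, j] = d[j, i] = (float(((m[i] != m[j]) & ok).sum()) / tot) if tot else 0.0
    return d


def logdet_distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Log-det (paralinear) distances, consistent under general time reversal.

    Saturated pairs (non-positive determinant) are capped at a large
    finite distance.
    """
    m = aln.matrix
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] < 4) & (m[j] < 4)
            if ok.sum() == 0:
                d[i, j] = d[j, i] = _MAX_DIST
                continue
            F = np.zeros((4, 4))
            np.add.at(F, (m[i][ok].astype(np.int64), m[j][ok].astype(np.int64)), 1)
            F = F / F.sum() + 1e-10
            fa, fb = F.sum(axis=1), F.sum(axis=0)
            det = np.linalg.det(F)
            if det <= 0:
                dist = _MAX_DIST
            else:
                dist = -0.25 * (np.log(det) - 0.5 * (np.log(fa).sum() + np.log(fb).sum()))
                dist = float(np.clip(dist, 0.0, _MAX_DIST))
            d[i, j] = d[j, i] = dist
    return d


def nj_tree(distances: np.ndarray, ids: list[str]) -> Node:
    """Neighbor-joining start tree (scikit-bio), as a trifurcating root."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    import io

    sk = skbio_nj(DistanceMatrix(distances, ids))
    buf = io.StringIO()
    sk.write(buf, format="newick")
    tree = Node.from_newick(buf.getvalue())
    for node in tree.postorder():
        node.length = max(node.length or 0.0, 0.0)
    tree = tree.suppress_unifurcations()
    return tree.unroot()


def _nni_neighbors(tree: Node):
    """Yield copies of ``tree`` differing by one nearest-neighbor interchange.

    For each internal edge (parent u, internal child v), the two
    rearrangements swap one child of v with v's first sibling.
    """
    nodes = [n for n in tree.postorder() if n is not tree and not n.is_leaf]
    for vi, _ in enumerate(nodes):
        for which in (0, 1):
            t = tree.copy()
            cand = [n for n in t.postorder() if n is not t and not n.is_leaf]
            v = cand[vi]
            u = v.parent
            sib = next(c for c in u.children if c is not v)
            child = v.children[which]
            ui, vi2 = u.children.index(sib), v.children.index(child)
            u.children[ui], v.children[vi2] = child, sib
            child.parent, sib.parent = u, v
            yield t


def _optimize_branch_lengths(tree: Node, aln: MultipleAlignment, model: PhyloModel,
                             tol: float = 1e-6, loglik_tol: float = 1e-4,
                             max_cycles: int = 10) -> float:
    """Cycle per-branch Brent optimization until the log-likelihood stalls."""
    current = gtr_gamma_loglik(aln, tree, model)
    for _ in range(max_cycles):
        previous = current
        for node in tree.postorder():
            if node is tree:
                continue

            def neg(x: float, node=node) -> float:
                node.length = x
                return -gtr_gamma_loglik(aln, tree, model)

            res = minimize_scalar(neg, bounds=(0.0, 10.0), method="bounded",
                                  options={"xatol": tol})
            node.length = float(res.x)
        current = gtr_gamma_loglik(aln, tree, model)
        if current - previous < loglik_tol:
            break
    return current


def _mp_branch_lengths(tree: Node, aln: MultipleAlignment) -> None:
    """Set branch lengths to per-branch parsimony step counts."""
    result = fitch_parsimony(aln, tree)
    for node in tree.postorder():
        if node is tree:
            continue
        key = frozenset(node.leaf_names())
        if key in result.branch_steps:
            node.length = float(result.branch_steps[key])


def search_tree(aln: MultipleAlignment, model: PhyloModel, method: str = "ML",
                seed: int = 0) -> Node:
    """NJ + first-improvement NNI hill climb under ML or MP.

    Taxa are sorted before the distance matrix is built so the result
    does not depend on input order; the seed fixes any remaining ties.
    """
    method = method.upper()
    if method not in ("ML", "MP"):
        raise ValueError("method must be 'ML' or 'MP'")
    ids = sorted(aln.ids)
    sub = MultipleAlignment(ids, np.vstack([aln.row(t) for t in ids]))
    if len(ids) < 4:
        tree = Node()
        for t in ids:
            tree.add_child(Node(t, 0.1))
        return tree

    if method == "ML":
        dist = logdet_distance_matrix(sub)
    else:
        dist = p_distance_matrix(sub)
    tree = nj_tree(dist, ids)

    def objective(t: Node, cycles: int = 10) -> float:
        if method == "ML":
            return _optimize_branch_lengths(t, sub, model, max_cycles=cycles)
        return -float(fitch_parsimony(sub, t).total_steps)

    best_score = objective(tree)
    improved = True
    while improved:
        improved = False
        for neighbor in _nni_neighbors(tree):
            # one branch-length cycle is enough to rank candidate topologies
            score = objective(neighbor, cycles=1)
            if score > best_score + 1e-9:
                tree, best_score = neighbor, objective(neighbor)
                improved = True
                break
    if method == "MP":
        _mp_branch_lengths(tree, sub)
    return tree


def bootstrap(aln: MultipleAlignment, model: PhyloModel, method: str = "MP",
              n_replicates: int = 1000, seed: int = 0,
              point_tree: Node | None = None) -> tuple[Node, dict[frozenset, float]]:
    """Column-resampling bootstrap supports for the point-estimate tree.

    Returns the point tree with per-node ``support`` set (percentage of
    replicates containing each bipartition) and the support map itself.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates >= 1 required")
    if point_tree is None:
        point_tree = search_tree(aln, model, method, seed)
    splits = point_tree.bipartitions()
    hits = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        replicate = MultipleAlignment(list(aln.ids), aln.matrix[:, cols])
        rep_tree = search_tree(replicate, model, method, seed)
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * h / n_replicates for s, h in hits.items()}
    all_names = frozenset(point_tree.leaf_names())
    anchor = min(all_names)
    for node in point_tree.postorder():
        if node is point_tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_names - side
        if side in support:
            node.support = support[side]
    return point_tree, support


def root_with_outgroup(tree: Node, outgroup_id: str) -> Node:
    """Root on the outgroup's pendant edge (midpoint of that edge).

    Idempotent: re-rooting an already outgroup-rooted tree returns the
    same topology.
    """
    names = tree.leaf_names()
    if outgroup_id not in names:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    t = tree.copy()
    og = t.find(outgroup_id)
    parent = og.parent
    if parent is None:
        raise ValueError("cannot root a single-leaf tree")
    if parent is t and len(t.children) == 2:
        return t  # already rooted on this pendant edge
    half = og.length / 2
    parent.children.remove(og)
    new_root = Node()
    new_root.add_child(og)
    og.length = half

    node, prev, carry = parent, new_root, half
    while node is not None:
        upper = node.parent
        node_len = node.length
        if upper is not None:
            upper.children.remove(node)
        prev.add_child(node)
        node.length = carry
        prev, carry, node = node, node_len, upper
    return new_root.suppress_unifurcations()
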