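"""Felsenstein pruning log-likelihood under GTR+G+I.

Site likelihood = p_inv * (invariant-compatible term) + (1 - p_inv) *
mean over the gamma categories of the pruning likelihood at that
category's rate.  Sites are compressed to unique patterns; N and gap
characters are treated as missing data (all-ones partials).
"""

from __future__ import annotations

import numpy as np

from .alignment import MultipleAlignment
from .model import PhyloModel
from .tree import Node


def _site_patterns(aln: MultipleAlignment
                   ) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Compress to unique site patterns; cached on the alignment object."""
    cache = getattr(aln, "_pattern_cache", None)
    if cache is None:
        order = sorted(aln.ids)
        rows = np.vstack([aln.row(t) for t in order])
        matrix, weights = np.unique(rows, axis=1, return_counts=True)
        cache = ({t: matrix[i] for i, t in enumerate(order)},
                 matrix, weights.astype(float))
        aln._pattern_cache = cache
    return cache


def _pruning_partials(tree: Node, patterns: dict[str, np.ndarray],
                      model: PhyloModel, rate: float) -> np.ndarray:
    """Root partial likelihoods, shape (n_patterns, 4)."""
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            codes = patterns[node.name]
            p = np.zeros((len(codes), 4))
            known = codes < 4
            p[known, codes[known].astype(np.int64)] = 1.0
            p[~known] = 1.0                       # N / gap: missing data
            partial[id(node)] = p
        else:
            p = np.ones((next(iter(partial.values())).shape[0], 4))
            for child in node.children:
                if child.length < 0:
                    raise ValueError("branch length must be >= 0")
                P = model.transition_matrix(child.length * rate)
                p *= partial.pop(id(child)) @ P.T
            partial[id(node)] = p
    return partial[id(tree)]


def _invariant_term(pattern_matrix: np.ndarray, model: PhyloModel) -> np.ndarray:
    """Per-pattern P(site | invariant): sum_x pi_x * [all taxa compatible with x]."""
    out = np.zeros(pattern_matrix.shape[1])
    for x in range(4):
        compatible = ((pattern_matrix == x) | (pattern_matrix > 3)).all(axis=0)
        out += model.frequencies[x] * compatible
    return out


def gtr_gamma_loglik(aln: MultipleAlignment, tree: Node, model: PhyloModel) -> float:
    """Log-likelihood of the alignment on the tree under the model."""
    taxa = tree.leaf_names()
    missing = set(taxa) - set(aln.ids)
    if missing:
        raise ValueError(f"taxa absent from alignment: {sorted(missing)}")
    patterns, pattern_matrix, weights = _site_patterns(aln)
    rates = model.variable_rates()
    site_lik = np.zeros(pattern_matrix.shape[1])
    for rate in rates:
        root = _pruning_partials(tree, patterns, model, rate)
        site_lik += (root * model.frequencies[None, :]).sum(axis=1)
    site_lik *= (1.0 - model.p_invariant) / len(rates)
    if model.p_invariant > 0:
        site_lik += model.p_invariant * _invariant_term(pattern_matrix, model)
    if np.any(site_lik <= 0):
        return -np.inf
    return float(weights @ np.log(site_lik))
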