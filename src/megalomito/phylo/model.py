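"""GTR+G+I nucleotide substitution model.

The general time-reversible rate matrix is parameterized by six
exchangeabilities (AC, AG, AT, CG, CT, GT) and stationary base
frequencies, normalized to one expected substitution per site per unit
branch length.  Among-site rate variation uses a discrete gamma with
``n_categories`` equal-probability classes (category rate = mean of its
quantile bin, the standard mean-of-quantile discretization) plus an
optional proportion of invariant sites; variable-category rates are
rescaled by 1/(1-p_inv) so the overall mean rate stays exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincinv, gammainc

BASE_ORDER = "ACGT"


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-of-quantile discretization of Gamma(alpha, mean 1)."""
    if alpha <= 0 or n_categories < 1:
        raise ValueError("alpha > 0 and n_categories >= 1 required")
    probs = np.arange(1, n_categories) / n_categories
    bounds = gammaincinv(alpha, probs) / alpha          # quantile boundaries
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; a<X<b] for Gamma(alpha, rate alpha) = F_{alpha+1}(b) - F_{alpha+1}(a)
    cum = lambda x: np.where(np.isinf(x), 1.0, gammainc(alpha + 1, alpha * x))
    rates = n_categories * (cum(upper) - cum(lower))
    return rates / rates.mean()  # exact mean-1 against roundoff


@dataclass
class PhyloModel:
    """GTR+G+I parameters; defaults give Jukes-Cantor with 5-category gamma."""

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))           # AC, AG, AT, CG, CT, GT
    frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    alpha: float | None = 0.3366
    n_categories: int = 5
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be > 0")
        if not np.isclose(self.frequencies.sum(), 1.0) or np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant in [0, 1) required")
        self._decompose()

    @classmethod
    def jc(cls, alpha: float | None = None, n_categories: int = 1,
           p_invariant: float = 0.0) -> "PhyloModel":
        return cls(np.ones(6), np.full(4, 0.25), alpha, n_categories, p_invariant)

    # -- rate matrix ---------------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Normalized GTR Q: rows sum to 0, -sum(pi_i * Q_ii) = 1."""
        s = self.exchangeabilities
        pi = self.frequencies
        S = np.zeros((4, 4))
        S[0, 1], S[0, 2], S[0, 3] = s[0], s[1], s[2]
        S[1, 2], S[1, 3], S[2, 3] = s[3], s[4], s[5]
        S = S + S.T
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _decompose(self) -> None:
        pi = self.frequencies
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = sq[:, None] * Q / sq[None, :]         # diag(sqrt pi) Q diag(1/sqrt pi)
        w, U = np.linalg.eigh(B)
        self._eigvals = w
        self._left = U.T * sq[None, :]            # U^T diag(sqrt(pi))
        self._right = U / sq[:, None]             # diag(1/sqrt(pi)) U

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are stochastic for all t >= 0."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        return np.clip(P, 0.0, None) / np.clip(P, 0.0, None).sum(axis=1, keepdims=True)

    # -- rate categories ------------------------------------------------
    def variable_rates(self) -> np.ndarray:
        """Rates of the gamma categories, scaled for +I so the overall mean is 1."""
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.n_categories)
        return rates / (1.0 - self.p_invariant)

    def category_rates(self) -> np.ndarray:
        """All categories including the invariant (rate-0) one when p_inv > 0."""
        rates = self.variable_rates()
        if self.p_invariant > 0:
            rates = np.concatenate([[0.0], rates])
        return rates

    def category_probs(self) -> np.ndarray:
        k = 1 if self.alpha is None else self.n_categories
        probs = np.full(k, (1.0 - self.p_invariant) / k)
        if self.p_invariant > 0:
            probs = np.concatenate([[self.p_invariant], probs])
        return probs
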