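"""HKY85 substitution model with discrete-gamma rate variation.

The HKY generator distinguishes transitions (A<->G, C<->T, weighted by
kappa) from transversions and allows arbitrary stationary base frequencies
pi.  The generator is scaled so the mean substitution rate at stationarity
is one, which makes branch "distances" expected substitutions per site and
branch rates substitutions per site per time unit.

Among-site rate variation uses the mean-of-category discretization of a
Gamma(alpha, alpha) density (mean 1) into K equal-probability classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["HKYParams", "HKYModel", "gamma_category_rates", "transition_matrix"]

# state order A, C, G, T; transitions are A<->G and C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True


@dataclass(frozen=True)
class HKYParams:
    kappa: float = 2.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 0.5
    n_cats: int = 4

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        p = np.asarray(self.pi, dtype=float)
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be positive and sum to 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_cats < 1:
            raise ValueError("n_cats must be >= 1")


def gamma_category_rates(alpha: float, n_cats: int) -> np.ndarray:
    """Mean rate of each of K equal-probability Gamma(alpha, alpha) classes.

    With X ~ Gamma(alpha, rate alpha) (mean 1) and class boundaries at the
    i/K quantiles, the class mean is K * [I(alpha+1, a*q_hi) - I(alpha+1, a*q_lo)]
    where I is the regularized lower incomplete gamma function.  The rates
    average to exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_cats == 1:
        return np.ones(1)
    probs = np.arange(1, n_cats) / n_cats
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([alpha * bounds, [np.inf]])
    lower = np.concatenate([[0.0], alpha * bounds])
    rates = n_cats * (gammainc(alpha + 1.0, upper) - gammainc(alpha + 1.0, lower))
    return rates


class HKYModel:
    """HKY transition probabilities via symmetric eigendecomposition.

    Reversibility makes ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` symmetric, so
    the spectral decomposition is computed once and P(d) = U exp(L d) U^-1
    costs a couple of small matrix products per branch.
    """

    def __init__(self, params: HKYParams):
        self.params = params
        pi = np.asarray(params.pi, dtype=float)
        self.pi = pi
        rates = np.where(_TRANSITION, params.kappa, 1.0)
        Q = rates * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale to one expected substitution per site per unit distance
        mean_rate = -(pi * np.diag(Q)).sum()
        Q /= mean_rate
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((S + S.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]      # D^-1/2 V
        self._right = (eigvec * sqrt_pi[:, None]).T  # V^T D^1/2
        self.category_rates = gamma_category_rates(params.alpha, params.n_cats)

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = exp(Q d) for distance d >= 0 (expected substitutions/site)."""
        if d < 0:
            raise ValueError("negative branch distance")
        if d == 0.0:
            return np.eye(4)
        P = (self._left * np.exp(self._eigval * d)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P

    def category_tpms(self, d: float) -> np.ndarray:
        """One TPM per gamma category: P(d * r_k), shape (K, 4, 4)."""
        if d < 0:
            raise ValueError("negative branch distance")
        if d == 0.0:
            return np.broadcast_to(
                np.eye(4), (len(self.category_rates), 4, 4)
            ).copy()
        ex = np.exp(np.multiply.outer(d * self.category_rates, self._eigval))
        P = (self._left[None, :, :] * ex[:, None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def transition_matrix(params: HKYParams, d: float) -> np.ndarray:
    """Convenience one-shot TPM (builds the decomposition each call)."""
    return HKYModel(params).transition_matrix(d)


def branch_tpms(
    tree, branch_rates: dict[int, float], model: HKYModel
) -> dict[int, np.ndarray]:
    """TPMs for every branch (keyed by child node id), all gamma categories.

    Branch distance = (parent_age - child_age) * branch_rate * category_rate.
    """
    out = {}
    for node in tree.nodes:
        if node.parent is None:
            continue
        duration = tree.nodes[node.parent].age - node.age
        if duration < 0:
            raise ValueError(f"negative duration on branch above node {node.id}")
        out[node.id] = model.category_tpms(duration * branch_rates[node.id])
    return out
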