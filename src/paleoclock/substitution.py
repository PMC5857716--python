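"""Poisson amino-acid substitution model with discrete-gamma rate heterogeneity.

The Poisson (equal-input) model has equal exchangeabilities between all 20
amino acids and uniform stationary frequencies (1/20).  Its transition
probabilities are available in closed form: for an expected number of
substitutions per site *d*,

    p_same(d) = 1/20 + (19/20) * exp(-(20/19) d)
    p_diff(d) = (1 - p_same(d)) / 19

Among-site rate variation uses the standard discrete-gamma approximation:
four equal-probability categories, each represented by its conditional mean
rate, so category rates always average exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "N_STATES",
    "AMINO_ACID_ORDER",
    "SubstitutionModel",
    "discrete_gamma_rates",
    "p_same",
    "transition_prob",
]

N_STATES = 20
AMINO_ACID_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACID_ORDER)}
MISSING_CODE = N_STATES  # gaps and 'X' are missing data


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-category discrete gamma rates (equal category probabilities).

    Category boundaries are gamma quantiles at k/n; each category's rate is
    the conditional mean of a Gamma(alpha, mean 1) variate in its bin, so the
    rates average to 1 for any alpha.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    k = n_categories
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([cuts, [np.inf]])
    lower = np.concatenate([[0.0], cuts])
    # E[X; a<X<b] for Gamma(alpha, mean 1) = I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    mass = gammainc(alpha + 1.0, alpha * upper) - gammainc(alpha + 1.0, alpha * lower)
    return k * mass


def p_same(length: float | np.ndarray) -> float | np.ndarray:
    """Probability that start and end states coincide after ``length`` subs/site."""
    K = N_STATES
    return 1.0 / K + (K - 1.0) / K * np.exp(-(K / (K - 1.0)) * np.asarray(length))


def transition_prob(length: float, category_rate: float = 1.0) -> np.ndarray:
    """20x20 transition-probability matrix of the Poisson model.

    ``length`` is the expected substitutions per site at unit rate; the
    effective length is ``length * category_rate``.
    """
    if length < 0:
        raise ValueError("branch length must be non-negative")
    d = length * category_rate
    ps = float(p_same(d))
    pd_ = (1.0 - ps) / (N_STATES - 1)
    P = np.full((N_STATES, N_STATES), pd_)
    np.fill_diagonal(P, ps)
    return P


def rate_matrix() -> np.ndarray:
    """Normalised Poisson generator (expected 1 substitution per unit length)."""
    K = N_STATES
    Q = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(Q, -1.0)
    return Q


@dataclass(frozen=True)
class SubstitutionModel:
    """Poisson exchange model with n_categories discrete-gamma site rates."""

    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def transition_prob(self, length: float, category_rate: float = 1.0) -> np.ndarray:
        return transition_prob(length, category_rate)


def encode_sequence(seq: str) -> np.ndarray:
    """Map an aligned amino-acid string to integer codes (missing = 20)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(ch, MISSING_CODE)
    return out
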