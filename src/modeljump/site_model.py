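"""Sampled site-model state and its concrete rate matrix / rate-category mixture.

The site model combines four averaged ingredients: a substitution-rate
grouping (:class:`~modeljump.model_space.ModelId`), gamma-distributed rate
heterogeneity across sites (indicator + shape alpha), a proportion of
invariable sites (indicator + p_inv), and equal versus estimated base
frequencies (indicator + simplex point).

Two normalization conventions hold throughout:

* the six expanded exchangeability rates always sum to 6 (identifiability of
  the relative rates), i.e. sum over groups of group_size * group_rate = 6;
* the instantaneous rate matrix and the category mixture are scaled to unit
  expected substitution rate, so branch lengths stay in expected
  substitutions per site regardless of the sampled site model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammainc, gammaincinv

from .model_space import ModelId

__all__ = [
    "SiteModelState",
    "RateMatrix",
    "CategoryMixture",
    "expand_rates",
    "build_rate_matrix",
    "gamma_category_rates",
    "category_mixture",
    "EQUAL_FREQS",
]

EQUAL_FREQS = np.full(4, 0.25)

_RATE_SUM = 6.0
_SUM_TOL = 1e-8


class SiteModelState:
    """Full sampled state of the averaged site model.

    alpha and p_inv always carry values but only influence the likelihood
    and posterior while their binary indicator is set; when has_est_freqs is
    0 the frequencies are pinned at (1/4, 1/4, 1/4, 1/4).
    """

    __slots__ = (
        "model",
        "group_rates",
        "has_gamma",
        "alpha",
        "has_inv",
        "p_inv",
        "has_est_freqs",
        "freqs",
        "k",
    )

    def __init__(
        self,
        model: ModelId,
        group_rates: Sequence[float],
        has_gamma: int = 0,
        alpha: float = 1.0,
        has_inv: int = 0,
        p_inv: float = 0.1,
        has_est_freqs: int = 0,
        freqs: Optional[Sequence[float]] = None,
        k: int = 4,
    ):
        self.model = model
        self.group_rates = np.asarray(group_rates, dtype=float)
        self.has_gamma = int(has_gamma)
        self.alpha = float(alpha)
        self.has_inv = int(has_inv)
        self.p_inv = float(p_inv)
        self.has_est_freqs = int(has_est_freqs)
        if freqs is None:
            freqs = EQUAL_FREQS
        self.freqs = np.asarray(freqs, dtype=float)
        self.k = int(k)

    def copy(self) -> "SiteModelState":
        return SiteModelState(
            self.model,
            self.group_rates.copy(),
            self.has_gamma,
            self.alpha,
            self.has_inv,
            self.p_inv,
            self.has_est_freqs,
            self.freqs.copy(),
            self.k,
        )

    def expanded_rates(self) -> np.ndarray:
        """The six exchangeability rates (ac, ag, at, cg, ct, gt)."""
        return expand_rates(self.model, self.group_rates)

    def rate_sum(self) -> float:
        sizes = np.asarray(self.model.group_sizes, dtype=float)
        return float(sizes @ self.group_rates)

    def validate(self, tol: float = _SUM_TOL) -> None:
        if len(self.group_rates) != self.model.n_groups:
            raise ValueError("group_rates length does not match the model's group count")
        if np.any(self.group_rates <= 0):
            raise ValueError("group rates must be positive")
        if abs(self.rate_sum() - _RATE_SUM) > tol:
            raise ValueError(f"expanded rates must sum to {_RATE_SUM}, got {self.rate_sum()}")
        if np.any(self.freqs <= 0) or abs(self.freqs.sum() - 1.0) > tol:
            raise ValueError("frequencies must be positive and sum to 1")
        if not self.has_est_freqs and np.any(np.abs(self.freqs - 0.25) > tol):
            raise ValueError("equal-frequency state must have freqs = 1/4")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.k < 2:
            raise ValueError("k must be at least 2")

    def __repr__(self) -> str:
        return (
            f"SiteModelState(model={self.model}, G={self.has_gamma}, I={self.has_inv}, "
            f"F={self.has_est_freqs}, alpha={self.alpha:.4g}, p_inv={self.p_inv:.4g})"
        )


@dataclass(frozen=True)
class RateMatrix:
    """A 4x4 instantaneous rate matrix and the normalizer that was divided out."""

    Q: np.ndarray
    scale: float


@dataclass(frozen=True)
class CategoryMixture:
    """Site-rate mixture: per-category (weight, rate), unit mean rate overall.

    The invariable category, when present, comes first and has rate exactly 0.
    """

    weights: np.ndarray
    rates: np.ndarray

    def __iter__(self):
        return iter(zip(self.weights, self.rates))

    def __len__(self) -> int:
        return len(self.weights)


def expand_rates(model: ModelId, group_rates: Sequence[float]) -> np.ndarray:
    """Expand per-group rates to the six positional rates (ac..gt).

    Raises if the rates are non-positive or the size-weighted sum deviates
    from 6 beyond tolerance.
    """
    gr = np.asarray(group_rates, dtype=float)
    if len(gr) != model.n_groups:
        raise ValueError(
            f"model {model} has {model.n_groups} groups but {len(gr)} rates were given"
        )
    if np.any(gr <= 0):
        raise ValueError("group rates must be positive")
    sizes = np.asarray(model.group_sizes, dtype=float)
    total = float(sizes @ gr)
    if abs(total - _RATE_SUM) > _SUM_TOL:
        raise ValueError(f"size-weighted rate sum must be {_RATE_SUM}, got {total}")
    return gr[np.asarray(model.labels)]


# (i, j) -> position in RATE_ORDER for the upper triangle of the 4x4 matrix
_PAIR_TO_POS = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}


def build_rate_matrix(
    rates: Sequence[float], freqs: Sequence[float], normalize: bool = True
) -> RateMatrix:
    """Assemble the reversible rate matrix Q_ij = pi_j * r_ij (i != j).

    Diagonal entries make rows sum to zero.  With ``normalize`` the matrix is
    divided by its expected rate mu = -sum_i pi_i Q_ii so that branch lengths
    measure expected substitutions per site; ``scale`` records mu.
    """
    r = np.asarray(rates, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if r.shape != (6,) or np.any(r < 0):
        raise ValueError("need six non-negative exchangeability rates")
    if not np.any(r > 0):
        raise ValueError("all exchangeability rates are zero")
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be a positive 4-simplex point")
    Q = np.zeros((4, 4))
    for (i, j), pos in _PAIR_TO_POS.items():
        Q[i, j] = pi[j] * r[pos]
        Q[j, i] = pi[i] * r[pos]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = float(-(pi * np.diag(Q)).sum())
    if normalize:
        Q = Q / mu
    return RateMatrix(Q=Q, scale=mu)


def gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Discretize a unit-mean gamma distribution into k equal-weight rates.

    Uses the mean-of-each-quantile-bin rule: the distribution Gamma(shape
    alpha, scale 1/alpha) is cut at its i/k quantiles and each category rate
    is the conditional mean within its bin, so the rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 2:
        raise ValueError("k must be at least 2")
    p = np.arange(1, k) / k
    # Quantiles of Gamma(alpha, scale=1/alpha): gammaincinv solves the
    # regularized lower incomplete gamma P(alpha, x) = p.
    cuts = gammaincinv(alpha, p) / alpha
    # E[X; X in bin] for Gamma(a, 1/a) is P(a+1, a*q_hi) - P(a+1, a*q_lo).
    edges = np.concatenate([[0.0], alpha * cuts, [np.inf]])
    mass = gammainc(alpha + 1.0, edges[1:]) - gammainc(alpha + 1.0, edges[:-1])
    rates = k * mass
    # remove the last trace of floating-point drift from the unit mean
    return rates / rates.mean()


def category_mixture(state: SiteModelState) -> CategoryMixture:
    """Turn the indicator flags, alpha and p_inv into an explicit rate mixture.

    Without flags this is the single category (1, 1).  With gamma, the k
    unit-mean gamma rates.  With invariable sites, a rate-0 category of
    weight p_inv is prepended and the non-zero rates are inflated by
    1/(1-p_inv) so the overall mean rate stays 1.
    """
    if state.p_inv >= 1.0:
        raise ValueError("p_inv must be below 1")
    if state.has_gamma:
        nz_rates = gamma_category_rates(state.alpha, state.k)
        nz_weights = np.full(state.k, 1.0 / state.k)
    else:
        nz_rates = np.array([1.0])
        nz_weights = np.array([1.0])
    if state.has_inv:
        p = state.p_inv
        weights = np.concatenate([[p], (1.0 - p) * nz_weights])
        rates = np.concatenate([[0.0], nz_rates / (1.0 - p)])
    else:
        weights, rates = nz_weights, nz_rates
    return CategoryMixture(weights=weights, rates=rates)
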