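"""Log prior densities for every site-model component, and prior sampling.

Default hyperparameters:

* rate prior: flat (Dirichlet-type) on the sum-to-6 rate surface, or the
  transition/transversion-informed alternative — log-normal with real-space
  mean 1 and log-scale standard deviation 1.25 on transition rates,
  exponential with mean 1 on transversion rates;
* base frequencies: symmetric Dirichlet(4,4,4,4) — concentrated enough that
  the chance of any frequency falling below 0.05 is only about 2.2%;
* proportion of invariable sites: Beta(1,4), mean 0.2;
* gamma shape alpha: exponential with mean 1;
* each binary indicator (gamma, invariable sites, estimated frequencies):
  Bernoulli(1/2), making the four site-model variants equiprobable a priori.

The alpha, p_inv and frequency priors only enter the posterior while the
matching indicator is set.

Rate prior on the constrained surface
-------------------------------------
Group rates live on the surface {sum_g n_g r_g = 6}.  In the mass
coordinates s_g = n_g r_g the flat prior is the *normalized* uniform density
on the scaled simplex {s_g > 0, sum s_g = 6}: log (G-1)! - (G-1) log 6 for a
model with G groups.  Normalizing per model is what makes a prior-sampling
chain visit every model with exactly its model-prior probability.  The
transition/transversion prior is evaluated as the product of per-position
densities of the six expanded rates, unnormalized on the surface (its
per-model normalizers have no closed form); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .model_space import ModelId, ModelSet, TRANSITION_POSITIONS, model_log_prior
from .site_model import EQUAL_FREQS, SiteModelState

__all__ = ["PriorConfig", "log_prior", "sample_prior"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of all component priors (see module docstring)."""

    rate_prior: str = "flat_dirichlet"  # or "tstv"
    model_prior: str = "uniform_models"  # or "uniform_dof"
    ts_mean: float = 1.0  # real-space mean of the transition-rate log-normal
    ts_sdlog: float = 1.25  # std dev of the log transition rate
    tv_mean: float = 1.0  # mean of the transversion-rate exponential
    freq_concentration: float = 4.0  # symmetric Dirichlet parameter
    pinv_a: float = 1.0
    pinv_b: float = 4.0
    alpha_mean: float = 1.0
    indicator_p: float = 0.5  # prior inclusion probability of each flag

    def __post_init__(self) -> None:
        if self.rate_prior not in ("flat_dirichlet", "tstv"):
            raise ValueError(f"unknown rate prior {self.rate_prior!r}")
        for name in ("ts_mean", "ts_sdlog", "tv_mean", "freq_concentration", "pinv_a", "pinv_b", "alpha_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.indicator_p < 1:
            raise ValueError("indicator_p must lie in (0,1)")


def _log_exponential(x: float, mean: float) -> float:
    if x <= 0:
        return -math.inf
    return -math.log(mean) - x / mean


def _log_lognormal(x: float, real_mean: float, sdlog: float) -> float:
    if x <= 0:
        return -math.inf
    mu = math.log(real_mean) - 0.5 * sdlog * sdlog
    z = (math.log(x) - mu) / sdlog
    return -math.log(x * sdlog) - 0.5 * (_LOG_2PI + z * z)


def _log_beta(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        return -math.inf
    return (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + (a - 1.0) * math.log(x)
        + (b - 1.0) * math.log1p(-x)
    )


def _log_dirichlet_sym(f: np.ndarray, conc: float) -> float:
    if np.any(f <= 0):
        return -math.inf
    k = len(f)
    return (
        math.lgamma(k * conc)
        - k * math.lgamma(conc)
        + (conc - 1.0) * float(np.log(f).sum())
    )


def rate_log_prior(state: SiteModelState, cfg: PriorConfig) -> float:
    """Log density of the group rates on the sum-to-6 surface."""
    gr = state.group_rates
    if np.any(gr <= 0):
        return -math.inf
    G = state.model.n_groups
    if cfg.rate_prior == "flat_dirichlet":
        # normalized uniform density on {s > 0, sum s = 6} in mass coordinates
        return math.lgamma(G) - (G - 1) * math.log(6.0)
    ts = set(TRANSITION_POSITIONS)
    total = 0.0
    for pos, r in zip(range(6), state.expanded_rates()):
        if pos in ts:
            total += _log_lognormal(float(r), cfg.ts_mean, cfg.ts_sdlog)
        else:
            total += _log_exponential(float(r), cfg.tv_mean)
    return total


def log_prior(state: SiteModelState, cfg: PriorConfig, model_set: ModelSet) -> float:
    """Joint log prior of a full site-model state.

    Returns -inf outside the support.  Component priors gated by an
    indicator contribute only while the indicator is set.
    """
    try:
        lp = model_log_prior(state.model, model_set, cfg.model_prior)
    except ValueError:
        return -math.inf
    lp += rate_log_prior(state, cfg)
    p = cfg.indicator_p
    for flag in (state.has_gamma, state.has_inv, state.has_est_freqs):
        lp += math.log(p if flag else 1.0 - p)
    if state.has_gamma:
        lp += _log_exponential(state.alpha, cfg.alpha_mean)
    if state.has_inv:
        lp += _log_beta(state.p_inv, cfg.pinv_a, cfg.pinv_b)
    if state.has_est_freqs:
        lp += _log_dirichlet_sym(state.freqs, cfg.freq_concentration)
    elif np.any(np.abs(state.freqs - 0.25) > 1e-9):
        return -math.inf
    return lp


def _sample_model(cfg: PriorConfig, model_set: ModelSet, rng: np.random.Generator) -> ModelId:
    models = model_set.models
    if cfg.model_prior == "uniform_models":
        return models[rng.integers(len(models))]
    weights = np.array(
        [1.0 / (len(model_set.dof_counts) * model_set.dof_counts[m.dof]) for m in models]
    )
    return models[rng.choice(len(models), p=weights / weights.sum())]


def _sample_group_rates(model: ModelId, cfg: PriorConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.asarray(model.group_sizes, dtype=float)
    G = model.n_groups
    if cfg.rate_prior == "flat_dirichlet":
        # exact draw: masses uniform on the scaled simplex
        s = 6.0 * rng.dirichlet(np.ones(G))
        return s / sizes
    # transition/transversion priors: draw each group's rate from the density
    # of its type and rescale onto the sum-to-6 surface (an approximation to
    # the exact conditional; see docs/methods.md).
    ts = set(TRANSITION_POSITIONS)
    raw = np.empty(G)
    for gi, grp in enumerate(model.groups):
        if all(p in ts for p in grp):
            mu = math.log(cfg.ts_mean) - 0.5 * cfg.ts_sdlog**2
            raw[gi] = rng.lognormal(mu, cfg.ts_sdlog)
        else:
            raw[gi] = rng.exponential(cfg.tv_mean)
    return raw * (6.0 / float(sizes @ raw))


def sample_prior(
    cfg: PriorConfig,
    model_set: ModelSet,
    rng: np.random.Generator,
    k: int = 4,
    force: Optional[Dict[str, int]] = None,
) -> SiteModelState:
    """Draw a full site-model state from the prior.

    ``force`` may clamp any of the indicators (``has_gamma``, ``has_inv``,
    ``has_est_freqs``) to a fixed value — used by the simulation studies to
    populate the plain/+G/+I/+G+I x equal/unequal design cells while all
    remaining parameters still come from their priors.
    """
    force = force or {}
    model = _sample_model(cfg, model_set, rng)
    group_rates = _sample_group_rates(model, cfg, rng)

    def flag(name: str) -> int:
        if name in force:
            return int(force[name])
        return int(rng.random() < cfg.indicator_p)

    has_gamma = flag("has_gamma")
    has_inv = flag("has_inv")
    has_est_freqs = flag("has_est_freqs")
    alpha = float(rng.exponential(cfg.alpha_mean))
    p_inv = float(rng.beta(cfg.pinv_a, cfg.pinv_b))
    if has_est_freqs:
        freqs = rng.dirichlet(np.full(4, cfg.freq_concentration))
    else:
        freqs = EQUAL_FREQS.copy()
    state = SiteModelState(
        model=model,
        group_rates=group_rates,
        has_gamma=has_gamma,
        alpha=alpha,
        has_inv=has_inv,
        p_inv=p_inv,
        has_est_freqs=has_est_freqs,
        freqs=freqs,
        k=k,
    )
    state.validate()
    return state
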