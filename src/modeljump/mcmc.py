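"""Reversible-jump MCMC kernel: proposals, acceptance rule, tuning, trace.

A proposal is accepted with probability

    min{1, posterior ratio x q(S|S') / q(S'|S) x |Jacobian|}

(the standard Metropolis-Hastings-Green rule; ``log_hastings`` below always
denotes log[q(S|S')/q(S'|S)] plus the log Jacobian of the dimension-matching
map).

Split/merge bookkeeping is done in mass coordinates s_g = n_g r_g, in which
the sum-to-6 constraint is the scaled simplex {sum s_g = 6}.  Splitting a
group of size n = n_i + n_j and rate r draws u uniformly on (-n_i r, n_j r)
and sets r_i = r + u/n_i, r_j = r - u/n_j — equivalently the mass s_i = n_i
r_i lands uniformly on (0, nr).  The reverse merge with r = (n_i r_i + n_j
r_j)/(n_i + n_j) is deterministic, so for a split from model M to child M'

    log_hastings = log(n r) + log|split_candidates(M)| - log|merge_candidates(M')|

with unit Jacobian in the mass chart (the normalized per-model rate prior
contributes the remaining dimension factor through the prior ratio; see
docs/methods.md for the derivation and for why this variant, rather than a
literal proposal-ratio-times-Jacobian transcription, leaves the prior
exactly invariant).  At the boundary models (nothing to split at the
all-free model, nothing to merge at the all-equal model) the proposal
returns the current state, which is required for uniform model sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .likelihood import ConstantLikelihood, DualTreeLikelihood, PatternTable, PhyloTree
from .model_space import ModelGraph, ModelSet
from .priors import (
    PriorConfig,
    _log_beta,
    _log_dirichlet_sym,
    _log_exponential,
    log_prior,
    sample_prior,
)
from .site_model import EQUAL_FREQS, SiteModelState

__all__ = [
    "ProposalOutcome",
    "ChainConfig",
    "split_rates",
    "merge_rates",
    "propose_split",
    "propose_merge",
    "propose_rate_exchange",
    "propose_gamma_birth_death",
    "propose_inv_birth_death",
    "propose_freq_flip",
    "propose_freq_walk",
    "propose_scale",
    "run_chain",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = (
    "Sample",
    "posterior",
    "likelihood",
    "prior",
    "model",
    "rateAC",
    "rateAG",
    "rateAT",
    "rateCG",
    "rateCT",
    "rateGT",
    "hasGammaRates",
    "gammaShape",
    "hasInvariableSites",
    "proportionInvariable",
    "hasEqualFreqs",
    "freqA",
    "freqC",
    "freqG",
    "freqT",
)


@dataclass
class ProposalOutcome:
    """Result of one proposal: new state, log Hastings+Jacobian term, validity.

    ``valid = False`` marks an automatic rejection (e.g. a negative rate);
    ``self_move = True`` marks a proposal that returns the current state
    unchanged (boundary model moves, or an operator whose indicator gate is
    closed), which is always accepted and never enters operator tuning.
    """

    proposed_state: SiteModelState
    log_hastings: float
    valid: bool
    self_move: bool = False


def split_rates(r: float, u: float, n_i: int, n_j: int) -> Tuple[float, float]:
    """The split map (r, u) -> (r_i, r_j) = (r + u/n_i, r - u/n_j).

    Mass is conserved: n_i r_i + n_j r_j = (n_i + n_j) r.  The absolute
    Jacobian determinant of this map is (n_i + n_j) / (n_i n_j).
    """
    return r + u / n_i, r - u / n_j


def merge_rates(r_i: float, r_j: float, n_i: int, n_j: int) -> float:
    """The merge map: size-weighted mean rate of the fused group."""
    return (n_i * r_i + n_j * r_j) / (n_i + n_j)


def propose_split(state: SiteModelState, graph: ModelGraph, rng: np.random.Generator) -> ProposalOutcome:
    """Split one rate group along a uniformly chosen graph edge."""
    m = state.model
    cands = graph.split_candidates(m)
    if not cands:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    child = cands[rng.integers(len(cands))]
    info = graph.split_info(m, child)
    n_i = child.group_sizes[info.child_i]
    n_j = child.group_sizes[info.child_j]
    r = float(state.group_rates[info.parent_group])
    s = (n_i + n_j) * r
    s_i = float(rng.uniform(0.0, s))
    if not 0.0 < s_i < s:
        return ProposalOutcome(state, -math.inf, False)
    new_rates = state.group_rates[list(info.child_to_parent)].copy()
    new_rates[info.child_i] = s_i / n_i
    new_rates[info.child_j] = (s - s_i) / n_j
    s2 = state.copy()
    s2.model = child
    s2.group_rates = new_rates
    log_h = math.log(s) + math.log(len(cands)) - math.log(len(graph.merge_candidates(child)))
    return ProposalOutcome(s2, log_h, True)


def propose_merge(state: SiteModelState, graph: ModelGraph, rng: np.random.Generator) -> ProposalOutcome:
    """Fuse two rate groups along a uniformly chosen reverse graph edge."""
    m = state.model
    cands = graph.merge_candidates(m)
    if not cands:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    parent = cands[rng.integers(len(cands))]
    info = graph.split_info(parent, m)
    n_i = m.group_sizes[info.child_i]
    n_j = m.group_sizes[info.child_j]
    r = merge_rates(
        float(state.group_rates[info.child_i]),
        float(state.group_rates[info.child_j]),
        n_i,
        n_j,
    )
    s = (n_i + n_j) * r
    new_rates = np.empty(parent.n_groups)
    for ci, pi in enumerate(info.child_to_parent):
        new_rates[pi] = state.group_rates[ci]
    new_rates[info.parent_group] = r
    s2 = state.copy()
    s2.model = parent
    s2.group_rates = new_rates
    log_h = math.log(len(cands)) - math.log(len(graph.split_candidates(parent))) - math.log(s)
    return ProposalOutcome(s2, log_h, True)


def propose_rate_exchange(
    state: SiteModelState, delta: float, rng: np.random.Generator
) -> ProposalOutcome:
    """Transfer rate mass between two groups, keeping the sum at 6.

    The transferred mass m is uniform on [0, delta]; with u = m/n_i the
    update is r_i' = r_i - u, r_j' = r_j + u n_i/n_j.  Drawn in the mass
    coordinate the kernel is symmetric, so the Hastings term is 0; the
    proposal fails (automatic reject) when r_i' < 0.
    """
    G = state.model.n_groups
    if G < 2:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    i = int(rng.integers(G))
    j = int(rng.integers(G - 1))
    if j >= i:
        j += 1
    sizes = state.model.group_sizes
    m_amt = float(rng.uniform(0.0, delta))
    r_i = float(state.group_rates[i]) - m_amt / sizes[i]
    r_j = float(state.group_rates[j]) + m_amt / sizes[j]
    if r_i <= 0.0:
        return ProposalOutcome(state, -math.inf, False)
    s2 = state.copy()
    s2.group_rates = state.group_rates.copy()
    s2.group_rates[i] = r_i
    s2.group_rates[j] = r_j
    return ProposalOutcome(s2, 0.0, True)


def propose_gamma_birth_death(
    state: SiteModelState, cfg: PriorConfig, rng: np.random.Generator
) -> ProposalOutcome:
    """Toggle gamma rate heterogeneity; on birth alpha is drawn fresh.

    The birth draw density d is the alpha prior (exponential, mean
    ``cfg.alpha_mean``); log_hastings is -log d(alpha') on birth and
    +log d(alpha) on death, with unit Jacobian.
    """
    s2 = state.copy()
    if state.has_gamma:
        s2.has_gamma = 0
        log_h = _log_exponential(state.alpha, cfg.alpha_mean)
    else:
        s2.has_gamma = 1
        s2.alpha = float(rng.exponential(cfg.alpha_mean))
        log_h = -_log_exponential(s2.alpha, cfg.alpha_mean)
    return ProposalOutcome(s2, log_h, True)


def propose_inv_birth_death(
    state: SiteModelState, cfg: PriorConfig, rng: np.random.Generator
) -> ProposalOutcome:
    """Toggle the invariable-sites category; on birth p_inv is drawn fresh."""
    s2 = state.copy()
    if state.has_inv:
        s2.has_inv = 0
        log_h = _log_beta(state.p_inv, cfg.pinv_a, cfg.pinv_b)
    else:
        s2.has_inv = 1
        s2.p_inv = float(rng.beta(cfg.pinv_a, cfg.pinv_b))
        log_h = -_log_beta(s2.p_inv, cfg.pinv_a, cfg.pinv_b)
    return ProposalOutcome(s2, log_h, True)


def propose_freq_flip(
    state: SiteModelState, cfg: PriorConfig, rng: np.random.Generator
) -> ProposalOutcome:
    """Toggle equal vs estimated base frequencies (birth draws from the prior)."""
    s2 = state.copy()
    if state.has_est_freqs:
        s2.has_est_freqs = 0
        s2.freqs = EQUAL_FREQS.copy()
        log_h = _log_dirichlet_sym(state.freqs, cfg.freq_concentration)
    else:
        s2.has_est_freqs = 1
        s2.freqs = rng.dirichlet(np.full(4, cfg.freq_concentration))
        log_h = -_log_dirichlet_sym(s2.freqs, cfg.freq_concentration)
    return ProposalOutcome(s2, log_h, True)


def propose_freq_walk(
    state: SiteModelState, rng: np.random.Generator, delta: float = 0.1
) -> ProposalOutcome:
    """Symmetric mass exchange between two frequencies (active only when estimated)."""
    if not state.has_est_freqs:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    i = int(rng.integers(4))
    j = int(rng.integers(3))
    if j >= i:
        j += 1
    m_amt = float(rng.uniform(0.0, delta))
    f = state.freqs.copy()
    f[i] -= m_amt
    f[j] += m_amt
    if f[i] <= 0.0:
        return ProposalOutcome(state, -math.inf, False)
    s2 = state.copy()
    s2.freqs = f
    return ProposalOutcome(s2, 0.0, True)


def propose_scale(
    value: float, scale_factor: float, rng: np.random.Generator
) -> Tuple[float, float]:
    """Multiplicative scale kernel: s ~ U(sf, 1/sf), log-Hastings = -log s."""
    if not 0.0 < scale_factor < 1.0:
        raise ValueError("scale_factor must lie in (0,1)")
    s = scale_factor + rng.random() * (1.0 / scale_factor - scale_factor)
    return value * s, -math.log(s)


def _propose_alpha_scale(
    state: SiteModelState, scale_factor: float, rng: np.random.Generator
) -> ProposalOutcome:
    # gated: only samples while the gamma category-count flag is set
    if not state.has_gamma:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    s2 = state.copy()
    s2.alpha, log_h = propose_scale(state.alpha, scale_factor, rng)
    return ProposalOutcome(s2, log_h, True)


def _propose_pinv_walk(
    state: SiteModelState, sigma: float, rng: np.random.Generator
) -> ProposalOutcome:
    # logit-space Gaussian walk respects the (0,1) support of p_inv
    if not state.has_inv:
        return ProposalOutcome(state, 0.0, True, self_move=True)
    p = state.p_inv
    z = math.log(p / (1.0 - p)) + sigma * float(rng.standard_normal())
    p2 = 1.0 / (1.0 + math.exp(-z))
    if not 0.0 < p2 < 1.0:
        return ProposalOutcome(state, -math.inf, False)
    s2 = state.copy()
    s2.p_inv = p2
    log_h = math.log(p2 * (1.0 - p2)) - math.log(p * (1.0 - p))
    return ProposalOutcome(s2, log_h, True)


@dataclass
class ChainConfig:
    """Chain length, seeding, operator weights and tuning parameters."""

    chain_length: int
    log_every: int = 100
    seed: int = 1
    burnin_frac: float = 0.1  # tuning window; summaries discard it too
    k: int = 4  # gamma categories
    target_acceptance: float = 0.234
    tune: bool = True
    delta: float = 1.5  # rate-exchange mass window
    scale_factor: float = 0.75  # alpha scale kernel
    pinv_sigma: float = 0.8  # logit-walk step for p_inv
    freq_delta: float = 0.1  # frequency mass-exchange window
    operator_weights: Optional[Dict[str, float]] = None
    sample_tree_heights: bool = False  # optional strict-clock node-height sampling
    yule_birth_rate: float = 5.5  # Yule prior rate when sampling heights

    def __post_init__(self) -> None:
        if self.chain_length <= 0:
            raise ValueError("chain_length must be positive")
        if self.log_every <= 0:
            raise ValueError("log_every must be positive")


_DEFAULT_WEIGHTS = {
    "split": 1.0,
    "merge": 1.0,
    "rate_exchange": 2.0,
    "gamma_toggle": 1.0,
    "inv_toggle": 1.0,
    "alpha_scale": 1.0,
    "pinv_walk": 1.0,
    "freq_flip": 1.0,
    "freq_walk": 1.0,
}
_TREE_WEIGHTS = {"node_slide": 3.0, "root_scale": 1.0}


class _Tunable:
    """Robbins-Monro log-scale adaptation toward a target acceptance rate."""

    def __init__(self, value: float, lo: float, hi: float, target: float):
        self.log_value = math.log(value)
        self.lo, self.hi, self.target = math.log(lo), math.log(hi), target
        self.attempts = 0

    @property
    def value(self) -> float:
        return math.exp(self.log_value)

    def update(self, accepted: bool) -> None:
        self.attempts += 1
        step = ((1.0 if accepted else 0.0) - self.target) / max(self.attempts, 10) ** 0.6
        self.log_value = min(self.hi, max(self.lo, self.log_value + step))


def yule_log_prior(internal_heights: np.ndarray, birth_rate: float) -> float:
    """Log density of the internal-node heights of a labeled Yule tree.

    With k lineages extant during an inter-node interval of duration d the
    interval contributes -k * birth_rate * d; each of the n-1 branching
    events contributes log birth_rate.
    """
    h = np.sort(np.asarray(internal_heights, dtype=float))[::-1]
    n = len(h) + 1  # taxa
    total = (n - 1) * math.log(birth_rate)
    bounds = np.concatenate([h, [0.0]])
    for m in range(n - 1):
        k = m + 2  # lineages between the m-th and (m+1)-th oldest nodes
        total -= birth_rate * k * (bounds[m] - bounds[m + 1])
    return total


class _HeightSampler:
    """Minimal strict-clock node-height sampling on a fixed ultrametric topology."""

    def __init__(self, tree: PhyloTree, birth_rate: float):
        self.tree = tree
        self.birth_rate = birth_rate
        self.heights = tree.node_heights()
        self.internal = [i for i in range(tree.n_nodes) if tree.children[i]]

    def blen(self, heights: Optional[np.ndarray] = None) -> np.ndarray:
        h = self.heights if heights is None else heights
        b = np.zeros(self.tree.n_nodes)
        for i in range(self.tree.n_nodes):
            p = self.tree.parent[i]
            if p >= 0:
                b[i] = h[p] - h[i]
        return b

    def log_prior(self, heights: Optional[np.ndarray] = None) -> float:
        h = self.heights if heights is None else heights
        return yule_log_prior(h[[i for i in self.internal]], self.birth_rate)

    def propose_slide(self, rng: np.random.Generator):
        cands = [i for i in self.internal if i != self.tree.root]
        if not cands:
            return None
        node = cands[int(rng.integers(len(cands)))]
        lo = max(self.heights[c] for c in self.tree.children[node])
        hi = self.heights[self.tree.parent[node]]
        h2 = self.heights.copy()
        h2[node] = rng.uniform(lo, hi)
        return h2, 0.0

    def propose_root_scale(self, scale_factor: float, rng: np.random.Generator):
        root = self.tree.root
        new_h, log_h = propose_scale(self.heights[root], scale_factor, rng)
        if new_h <= max(self.heights[c] for c in self.tree.children[root]):
            return None
        h2 = self.heights.copy()
        h2[root] = new_h
        return h2, log_h


def run_chain(
    patterns: Optional[PatternTable],
    tree: Optional[PhyloTree],
    model_set: ModelSet,
    prior_cfg: PriorConfig,
    chain_cfg: ChainConfig,
    init_state: Optional[SiteModelState] = None,
    likelihood=None,
) -> pd.DataFrame:
    """Run the reversible-jump chain and return the trace as a DataFrame.

    With ``patterns`` (and ``tree``) given, the alignment likelihood drives
    the posterior; with both omitted the likelihood is constant and the
    chain samples the prior — the decisive correctness check for every
    proposal.  The chain is fully reproducible from ``chain_cfg.seed``.
    """
    rng = np.random.default_rng(chain_cfg.seed)
    graph = model_set.graph
    if likelihood is None:
        if patterns is not None:
            if tree is None:
                raise ValueError("a tree is required when an alignment is given")
            likelihood = DualTreeLikelihood(tree, patterns)
        else:
            likelihood = ConstantLikelihood()

    state = init_state.copy() if init_state is not None else sample_prior(
        prior_cfg, model_set, rng, k=chain_cfg.k
    )
    state.validate()

    heights: Optional[_HeightSampler] = None
    if chain_cfg.sample_tree_heights:
        if tree is None:
            raise ValueError("tree-height sampling requires a tree")
        heights = _HeightSampler(tree, chain_cfg.yule_birth_rate)

    tun = {
        "rate_exchange": _Tunable(chain_cfg.delta, 1e-4, 6.0, chain_cfg.target_acceptance),
        "pinv_walk": _Tunable(chain_cfg.pinv_sigma, 1e-3, 10.0, chain_cfg.target_acceptance),
        "freq_walk": _Tunable(chain_cfg.freq_delta, 1e-4, 0.25, chain_cfg.target_acceptance),
        # the scale kernel is tuned through b = -log(scale factor)
        "alpha_scale": _Tunable(-math.log(chain_cfg.scale_factor), 1e-3, 5.0, chain_cfg.target_acceptance),
        "root_scale": _Tunable(-math.log(chain_cfg.scale_factor), 1e-3, 5.0, chain_cfg.target_acceptance),
    }

    weights = dict(_DEFAULT_WEIGHTS)
    if heights is not None:
        weights.update(_TREE_WEIGHTS)
    if chain_cfg.operator_weights:
        weights.update(chain_cfg.operator_weights)
    names = [n for n, w in weights.items() if w > 0]
    wsum = sum(weights[n] for n in names)
    cum = np.cumsum([weights[n] / wsum for n in names])

    def current_blen() -> Optional[np.ndarray]:
        return heights.blen() if heights is not None else None

    lp = log_prior(state, prior_cfg, model_set)
    if heights is not None:
        lp += heights.log_prior()
    ll = likelihood.log_likelihood(state, blen=current_blen())
    if not (math.isfinite(lp) and math.isfinite(ll)):
        raise RuntimeError(
            f"non-finite initial posterior (prior={lp}, likelihood={ll}); "
            "check the initial state against the prior support"
        )

    burnin = int(chain_cfg.burnin_frac * chain_cfg.chain_length)
    rows: List[tuple] = []

    def record(step: int) -> None:
        rates = state.expanded_rates()
        rows.append(
            (
                step,
                lp + ll,
                ll,
                lp,
                str(state.model),
                *rates,
                state.has_gamma,
                state.alpha,
                state.has_inv,
                state.p_inv,
                1 - state.has_est_freqs,
                *state.freqs,
            )
        )

    for step in range(chain_cfg.chain_length + 1):
        if step % chain_cfg.log_every == 0:
            record(step)
        if step == chain_cfg.chain_length:
            break
        name = names[int(np.searchsorted(cum, rng.random()))]
        new_heights = None
        if name == "split":
            out = propose_split(state, graph, rng)
        elif name == "merge":
            out = propose_merge(state, graph, rng)
        elif name == "rate_exchange":
            out = propose_rate_exchange(state, tun["rate_exchange"].value, rng)
        elif name == "gamma_toggle":
            out = propose_gamma_birth_death(state, prior_cfg, rng)
        elif name == "inv_toggle":
            out = propose_inv_birth_death(state, prior_cfg, rng)
        elif name == "alpha_scale":
            out = _propose_alpha_scale(state, math.exp(-tun["alpha_scale"].value), rng)
        elif name == "pinv_walk":
            out = _propose_pinv_walk(state, tun["pinv_walk"].value, rng)
        elif name == "freq_flip":
            out = propose_freq_flip(state, prior_cfg, rng)
        elif name == "freq_walk":
            out = propose_freq_walk(state, rng, tun["freq_walk"].value)
        elif name == "node_slide":
            res = heights.propose_slide(rng)
            if res is None:
                continue
            new_heights, log_h = res
            out = ProposalOutcome(state, log_h, True)
        elif name == "root_scale":
            res = heights.propose_root_scale(math.exp(-tun["root_scale"].value), rng)
            if res is None:
                out = ProposalOutcome(state, -math.inf, False)
            else:
                new_heights, log_h = res
                out = ProposalOutcome(state, log_h, True)
        else:  # pragma: no cover
            raise RuntimeError(f"unknown operator {name}")

        if out.self_move:
            continue

        accepted = False
        if out.valid:
            s2 = out.proposed_state
            lp2 = log_prior(s2, prior_cfg, model_set)
            if heights is not None:
                h2 = new_heights if new_heights is not None else heights.heights
                lp2 += heights.log_prior(h2)
            if math.isfinite(lp2):
                blen2 = heights.blen(new_heights) if heights is not None and new_heights is not None else current_blen()
                try:
                    ll2 = likelihood.log_likelihood(s2, blen=blen2)
                except ArithmeticError:
                    ll2 = -math.inf
                log_r = (lp2 + ll2) - (lp + ll) + out.log_hastings
                if log_r >= 0.0 or math.log(rng.random()) < log_r:
                    state, lp, ll = s2, lp2, ll2
                    if new_heights is not None:
                        heights.heights = new_heights
                    accepted = True
        if chain_cfg.tune and step < burnin and name in tun:
            tun[name].update(accepted)

    df = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    return df
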