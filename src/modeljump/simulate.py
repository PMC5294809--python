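"""Simulation of Yule trees and alignments under prior-drawn site models.

The validation studies draw a true site model from the prior (optionally
clamping the gamma / invariable-sites / frequency indicators to populate a
design cell), generate an alignment on a fixed or Yule-simulated tree under
a strict clock, run the reversible-jump chain on the result, and keep the
truth/trace pair for coverage analysis.  Everything is seeded end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .likelihood import PhyloTree, compress_patterns
from .mcmc import ChainConfig, run_chain
from .model_space import ModelSet
from .priors import PriorConfig, sample_prior
from .site_model import SiteModelState, build_rate_matrix, category_mixture

__all__ = [
    "SimulationDesign",
    "Replicate",
    "draw_birth_rate",
    "simulate_yule_tree",
    "simulate_alignment",
    "run_validation_study",
    "rate_recovery_study",
    "FIXED_3TAXON_NEWICK",
]

#: The fixed three-taxon validation tree.
FIXED_3TAXON_NEWICK = "(A:0.2,(B:0.15,C:0.15):0.05);"


@dataclass
class SimulationDesign:
    """One cell (or a whole grid) of the simulation study.

    ``forced_flags`` clamps indicators during the truth draw, e.g.
    ``{"has_gamma": 1, "has_inv": 0, "has_est_freqs": 1}`` is the "+G,
    unequal frequencies" cell; unlisted indicators stay prior-random.
    """

    tree_source: str = "fixed_newick"  # or "yule"
    newick: str = FIXED_3TAXON_NEWICK
    n_taxa: int = 5
    n_sites: int = 10_000
    birth_rate_mean: float = 5.5  # real-space mean of the log-normal birth rate
    birth_rate_sdlog: float = 0.048
    forced_flags: Dict[str, int] = field(default_factory=dict)
    replicates: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.replicates <= 0:
            raise ValueError("n_sites and replicates must be positive")
        if self.tree_source not in ("fixed_newick", "yule"):
            raise ValueError(f"unknown tree source {self.tree_source!r}")


def draw_birth_rate(rng: np.random.Generator, real_mean: float = 5.5, sdlog: float = 0.048) -> float:
    """Birth rate from a log-normal with the given real-space mean."""
    mu = math.log(real_mean) - 0.5 * sdlog * sdlog
    return float(rng.lognormal(mu, sdlog))


def simulate_yule_tree(n_taxa: int, birth_rate: float, rng: np.random.Generator) -> PhyloTree:
    """Simulate an ultrametric pure-birth tree conditioned on ``n_taxa`` tips.

    Starting from the root with two lineages, the process waits an
    Exponential(k * birth_rate) time while k lineages exist; after each wait
    with k < n_taxa a uniformly chosen lineage splits, and the wait at
    k = n_taxa ends at the present.  The expected root height is
    (1/birth_rate) * sum_{k=2..n} 1/k.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    # event bookkeeping: each active lineage is (start_time, node_record)
    # where node_record = [children list]; times run root -> present.
    t = 0.0
    root_children: List[dict] = []
    root = {"start": 0.0, "children": root_children, "end": None}
    active = []
    for _ in range(2):
        node = {"start": 0.0, "children": [], "end": None}
        root_children.append(node)
        active.append(node)
    for k in range(2, n_taxa + 1):
        t += float(rng.exponential(1.0 / (k * birth_rate)))
        if k == n_taxa:
            break
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node["end"] = t
        for _ in range(2):
            child = {"start": t, "children": [], "end": None}
            node["children"].append(child)
            active.append(child)
    present = t
    for node in active:
        node["end"] = present
    root["end"] = 0.0

    # flatten to PhyloTree arrays; leaves first, named t1..tn in simulation order
    leaves = active
    taxa = [f"t{i + 1}" for i in range(len(leaves))]
    index: Dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
    counter = len(leaves)

    def assign(node: dict) -> int:
        nonlocal counter
        if id(node) in index:
            return index[id(node)]
        for ch in node["children"]:
            assign(ch)
        index[id(node)] = counter
        counter += 1
        return index[id(node)]

    assign(root)
    n = counter
    parent = [-1] * n
    blen = [0.0] * n
    children: List[List[int]] = [[] for _ in range(n)]

    def walk(node: dict) -> None:
        i = index[id(node)]
        for ch in node["children"]:
            j = index[id(ch)]
            parent[j] = i
            blen[j] = ch["end"] - ch["start"]
            children[i].append(j)
            walk(ch)

    walk(root)
    return PhyloTree(taxa, parent, blen, children)


def _evolve_states(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw child states site-by-site from the rows of P indexed by the parent."""
    out = np.empty_like(parent_states)
    for v in range(4):
        idx = np.flatnonzero(parent_states == v)
        if len(idx):
            out[idx] = rng.choice(4, size=len(idx), p=P[v])
    return out


def simulate_alignment(
    tree: PhyloTree, state: SiteModelState, n_sites: int, rng: np.random.Generator
) -> Dict[str, str]:
    """Generate an alignment of ``n_sites`` columns under the site model.

    Each site draws a rate category from the mixture; zero-rate (invariable)
    sites copy a single root draw from the stationary frequencies to every
    taxon, other sites evolve down the tree with transition probabilities at
    the category rate.  Invariant columns produced by chance are left in.
    """
    state.validate()
    mix = category_mixture(state)
    rates6 = state.expanded_rates()
    freqs = state.freqs
    Q = build_rate_matrix(rates6, freqs, normalize=True).Q
    cats = rng.choice(len(mix), size=n_sites, p=mix.weights)
    seqs = np.empty((tree.n_leaves, n_sites), dtype=np.int8)
    from scipy.linalg import expm

    for c, rate in enumerate(mix.rates):
        sites = np.flatnonzero(cats == c)
        if len(sites) == 0:
            continue
        root_states = rng.choice(4, size=len(sites), p=freqs)
        if rate == 0.0:
            seqs[:, sites] = root_states[None, :]
            continue
        node_states: Dict[int, np.ndarray] = {tree.root: root_states}
        for node in reversed(tree.postorder):  # preorder: parents first
            if node == tree.root:
                continue
            P = expm(Q * (rate * tree.blen[node]))
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            node_states[node] = _evolve_states(node_states[tree.parent[node]], P, rng)
        for leaf in range(tree.n_leaves):
            seqs[leaf, sites] = node_states[leaf]
    bases = np.array(list("ACGT"))
    return {name: "".join(bases[row]) for name, row in zip(tree.taxa, seqs)}


@dataclass
class Replicate:
    """Truth/trace pair from one validation replicate."""

    truth: SiteModelState
    tree: PhyloTree
    trace: pd.DataFrame

    def truth_record(self) -> Dict[str, float]:
        r = self.truth.expanded_rates()
        return {
            "model": str(self.truth.model),
            "rateAC": r[0], "rateAG": r[1], "rateAT": r[2],
            "rateCG": r[3], "rateCT": r[4], "rateGT": r[5],
            "hasGammaRates": self.truth.has_gamma,
            "gammaShape": self.truth.alpha,
            "hasInvariableSites": self.truth.has_inv,
            "proportionInvariable": self.truth.p_inv,
            "hasEqualFreqs": 1 - self.truth.has_est_freqs,
            "freqA": self.truth.freqs[0], "freqC": self.truth.freqs[1],
            "freqG": self.truth.freqs[2], "freqT": self.truth.freqs[3],
        }


def run_validation_study(
    design: SimulationDesign,
    chain_cfg: ChainConfig,
    prior_cfg: PriorConfig,
    model_set: ModelSet,
    truth_prior_cfg: Optional[PriorConfig] = None,
) -> List[Replicate]:
    """Simulate ``design.replicates`` truth/alignment pairs and analyse each.

    ``truth_prior_cfg`` lets the generating prior differ from the analysis
    prior (it defaults to the analysis prior).  Each replicate gets an
    independent sub-seed derived from the design seed.
    """
    truth_prior = truth_prior_cfg if truth_prior_cfg is not None else prior_cfg
    master = np.random.default_rng(design.seed)
    out: List[Replicate] = []
    for rep in range(design.replicates):
        sub = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(sub)
        if design.tree_source == "fixed_newick":
            tree = PhyloTree.from_newick(design.newick)
        else:
            lam = draw_birth_rate(rng, design.birth_rate_mean, design.birth_rate_sdlog)
            tree = simulate_yule_tree(design.n_taxa, lam, rng)
        truth = sample_prior(truth_prior, model_set, rng, k=chain_cfg.k, force=design.forced_flags)
        aln = simulate_alignment(tree, truth, design.n_sites, rng)
        patterns = compress_patterns(aln)
        cfg = ChainConfig(**{**chain_cfg.__dict__, "seed": sub})
        trace = run_chain(patterns, tree, model_set, prior_cfg, cfg)
        out.append(Replicate(truth=truth, tree=tree, trace=trace))
    return out


_RATE_COLS = ["rateAC", "rateAG", "rateAT", "rateCG", "rateCT", "rateGT"]


def rate_recovery_study(
    model_set: ModelSet,
    prior_cfg: PriorConfig,
    n_replicates: int = 20,
    n_sites: int = 10_000,
    chain_length: int = 30_000,
    seed: int = 1,
    burnin_frac: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Accuracy study of substitution-rate estimates on the fixed 3-taxon tree.

    Half of the replicates are generated with gamma rate heterogeneity, half
    without; all other site-model components come from the prior.  Returns
    (true rates, posterior-mean rates), both of shape (n_replicates, 6), from
    which the per-rate squared correlation between truth and estimate is the
    headline accuracy figure.
    """
    from .summarize import apply_burnin

    truths, means = [], []
    half = n_replicates // 2
    for cell, (n_rep, gamma) in enumerate([(n_replicates - half, 0), (half, 1)]):
        design = SimulationDesign(
            tree_source="fixed_newick",
            n_sites=n_sites,
            forced_flags={"has_gamma": gamma, "has_inv": 0, "has_est_freqs": 1},
            replicates=n_rep,
            seed=seed + cell,
        )
        cfg = ChainConfig(
            chain_length=chain_length, log_every=max(1, chain_length // 2000), seed=seed
        )
        for rep in run_validation_study(design, cfg, prior_cfg, model_set):
            truths.append(rep.truth.expanded_rates())
            means.append(apply_burnin(rep.trace, burnin_frac)[_RATE_COLS].mean().to_numpy())
    return np.asarray(truths), np.asarray(means)
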