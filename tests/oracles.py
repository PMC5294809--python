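"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the likelihood oracle
sums explicitly over all internal-node state assignments with scipy's
matrix exponential, instead of pruning with the eigendecomposition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from modeljump.likelihood import IUPAC_CODES, PhyloTree
from modeljump.site_model import SiteModelState, build_rate_matrix, category_mixture


def brute_log_likelihood(tree: PhyloTree, alignment: dict, state: SiteModelState) -> float:
    """Explicit summation over all node-state assignments, per site."""
    mix = category_mixture(state)
    Q = build_rate_matrix(state.expanded_rates(), state.freqs, normalize=True).Q
    pi = state.freqs
    names = list(alignment)
    length = len(alignment[names[0]])
    leaf_index = {t: i for i, t in enumerate(tree.taxa)}
    nodes = list(range(tree.n_nodes))
    total = 0.0
    for site in range(length):
        site_lik = 0.0
        for w, rate in zip(mix.weights, mix.rates):
            if rate == 0.0:
                # invariable category: every taxon must be compatible with one base
                compat = np.ones(4)
                for t in names:
                    mask = np.zeros(4)
                    for b in IUPAC_CODES[alignment[t][site].upper()]:
                        mask[b] = 1.0
                    compat *= mask
                site_lik += w * float(compat @ pi)
                continue
            P = {n: expm(Q * (rate * tree.blen[n])) for n in nodes}
            cat_lik = 0.0
            for assign in itertools.product(range(4), repeat=tree.n_nodes):
                prob = pi[assign[tree.root]]
                ok = True
                for n in nodes:
                    p = tree.parent[n]
                    if p >= 0:
                        prob *= P[n][assign[p], assign[n]]
                    if not tree.children[n]:  # leaf: observed symbol must match
                        sym = alignment[tree.taxa[n]][site].upper()
                        if assign[n] not in IUPAC_CODES[sym]:
                            ok = False
                            break
                if ok:
                    cat_lik += prob
            site_lik += w * cat_lik
        total += np.log(site_lik)
    return float(total)
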