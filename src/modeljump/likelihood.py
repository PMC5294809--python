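"""Alignment likelihood on a rooted tree: pattern compression and pruning.

The likelihood of a nucleotide alignment under a reversible site model is
computed by Felsenstein's pruning algorithm on compressed site patterns.
Transition probabilities P(t) = exp(Qt) are obtained from the symmetrized
eigendecomposition of the reversible rate matrix, which is exact and lets
all branch/category matrices be formed in one vectorized pass.

Two computational shortcuts matter for the model-averaging sampler:

* the zero-rate (invariable) category is never evaluated by pruning — a
  pattern contributes p_inv * sum of pi_x over the bases x compatible with
  the pattern being constant, and 0 if no base is compatible;
* toggling gamma rate heterogeneity switches between a 1-category and a
  k-category evaluation, so :class:`DualTreeLikelihood` keeps one cache per
  configuration and a toggle never invalidates both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .site_model import SiteModelState, build_rate_matrix, category_mixture

__all__ = [
    "IUPAC_CODES",
    "PatternTable",
    "PhyloTree",
    "compress_patterns",
    "pruning_log_likelihood",
    "TreeLikelihood",
    "DualTreeLikelihood",
    "ConstantLikelihood",
]

#: IUPAC nucleotide symbols mapped to the set of compatible bases (A,C,G,T
#: as indices 0..3).  Gaps and ? are fully ambiguous.
IUPAC_CODES: Dict[str, Tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

BASES = "ACGT"

AlignmentLike = Union[Mapping[str, str], Sequence[Tuple[str, str]]]


def _as_pairs(alignment: AlignmentLike) -> List[Tuple[str, str]]:
    if isinstance(alignment, Mapping):
        return [(k, v) for k, v in alignment.items()]
    return [(k, v) for k, v in alignment]


@dataclass
class PatternTable:
    """Compressed alignment: unique site patterns with multiplicities.

    ``partials`` holds the per-taxon leaf partial likelihood vectors
    (n_taxa, n_patterns, 4): 1 for compatible bases, 0 otherwise.
    ``invariant_mask`` marks, per pattern and base, whether the pattern is
    compatible with being constant at that base (ambiguities resolved).
    """

    taxa: Tuple[str, ...]
    patterns: np.ndarray  # (n_patterns, n_taxa) uint8 symbol indices
    counts: np.ndarray  # (n_patterns,) positive ints
    partials: np.ndarray  # (n_taxa, n_patterns, 4) float
    invariant_mask: np.ndarray  # (n_patterns, 4) bool

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def n_patterns(self) -> int:
        return len(self.counts)

    def invariant_compat(self, p: int) -> Tuple[str, ...]:
        """Bases consistent with pattern ``p`` being an invariant column."""
        return tuple(BASES[i] for i in range(4) if self.invariant_mask[p, i])


_SYMBOLS = list(IUPAC_CODES)
_SYMBOL_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
_SYMBOL_PARTIALS = np.zeros((len(_SYMBOLS), 4))
for _s, _bases in IUPAC_CODES.items():
    for _b in _bases:
        _SYMBOL_PARTIALS[_SYMBOL_INDEX[_s], _b] = 1.0


def compress_patterns(alignment: AlignmentLike) -> PatternTable:
    """Collapse an alignment to its unique site patterns with counts."""
    pairs = _as_pairs(alignment)
    if not pairs:
        raise ValueError("empty alignment")
    taxa = tuple(name for name, _ in pairs)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon names in alignment")
    length = len(pairs[0][1])
    if length == 0:
        raise ValueError("alignment has zero length")
    rows = []
    for name, seq in pairs:
        if len(seq) != length:
            raise ValueError(f"ragged alignment: sequence {name!r} has length {len(seq)} != {length}")
        try:
            rows.append([_SYMBOL_INDEX[c] for c in seq.upper()])
        except KeyError as e:
            raise ValueError(f"unknown nucleotide symbol {e.args[0]!r} in sequence {name!r}") from None
    mat = np.asarray(rows, dtype=np.uint8)  # (n_taxa, n_sites)
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    partials = _SYMBOL_PARTIALS[patterns].transpose(1, 0, 2)  # (n_taxa, n_pat, 4)
    invariant_mask = partials.prod(axis=0) > 0  # base compatible with every taxon
    return PatternTable(
        taxa=taxa,
        patterns=patterns,
        counts=counts.astype(np.int64),
        partials=np.ascontiguousarray(partials),
        invariant_mask=invariant_mask,
    )


class PhyloTree:
    """A rooted phylogeny with branch lengths in expected substitutions/site.

    Leaves occupy node indices 0..n_leaves-1 in the order of ``taxa``;
    ``postorder`` lists every node after all of its children.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        parent: Sequence[int],
        blen: Sequence[float],
        children: Sequence[Sequence[int]],
    ):
        self.taxa = tuple(taxa)
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.children = [list(c) for c in children]
        roots = [i for i, p in enumerate(self.parent) if p < 0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in tree")
        if np.any(self.blen < 0):
            raise ValueError("negative branch length in tree")
        order: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        self.postorder = order

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "PhyloTree":
        leaves = [lf for lf in tree.leaf_node_iter()]
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise ValueError("tree has an unlabeled leaf")
        taxa = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        next_id = len(leaves)
        for node in tree.postorder_node_iter():
            if id(node) not in index:
                index[id(node)] = next_id
                next_id += 1
        n = next_id
        parent = [-1] * n
        blen = [0.0] * n
        children: List[List[int]] = [[] for _ in range(n)]
        for node in tree.postorder_node_iter():
            i = index[id(node)]
            el = node.edge.length
            if el is not None and el < 0:
                raise ValueError("negative branch length in tree")
            blen[i] = float(el) if el is not None else 0.0
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
        return cls(taxa, parent, blen, children)

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                label = self.taxa[i]
            else:
                label = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] < 0:
                return label
            return f"{label}:{self.blen[i]:.17g}"

        return rec(self.root) + ";"

    def node_heights(self, tol: float = 1e-9) -> np.ndarray:
        """Heights above the leaves; raises if the tree is not ultrametric."""
        depth = np.zeros(self.n_nodes)
        for i in reversed(self.postorder):  # preorder
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.blen[i]
        leaf_depths = depth[: self.n_leaves]
        total = leaf_depths.max()
        if np.any(np.abs(leaf_depths - total) > max(tol, 1e-7 * max(total, 1.0))):
            raise ValueError("tree is not ultrametric")
        return total - depth


def _transition_matrices(
    rates: np.ndarray, freqs: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """P(t) = exp(Qt) for every length in ``lengths`` via symmetric eigendecomposition."""
    Q = build_rate_matrix(rates, freqs, normalize=True).Q
    sq = np.sqrt(freqs)
    S = Q * (sq[:, None] / sq[None, :])
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    A = V / sq[:, None]  # D^{-1/2} V
    B = V.T * sq[None, :]  # V^T D^{1/2}
    E = np.exp(np.multiply.outer(lengths, lam))  # (..., 4)
    P = np.einsum("ik,...k,kj->...ij", A, E, B)
    np.clip(P, 0.0, None, out=P)
    return P


class TreeLikelihood:
    """Pruning log-likelihood of a fixed pattern table on a fixed tree."""

    def __init__(self, tree: PhyloTree, patterns: PatternTable):
        order = {name: i for i, name in enumerate(patterns.taxa)}
        if set(tree.taxa) != set(patterns.taxa):
            raise ValueError("tree taxa and alignment taxa differ")
        # leaf partials arranged in the tree's leaf order
        self.tree = tree
        self.patterns = patterns
        self._leaf_partials = patterns.partials[[order[t] for t in tree.taxa]]
        self._counts = patterns.counts.astype(float)
        self._inv_mask = patterns.invariant_mask.astype(float)

    def log_likelihood(self, state: SiteModelState, blen: Optional[np.ndarray] = None) -> float:
        """Site-pattern mixture log-likelihood under ``state``.

        ``blen`` optionally overrides the tree's branch lengths (used by the
        optional node-height sampler); the zero-rate invariable category is
        handled in closed form and never pruned.
        """
        tree = self.tree
        lengths = tree.blen if blen is None else blen
        mix = category_mixture(state)
        nz = mix.rates > 0
        nz_rates = mix.rates[nz]
        nz_weights = mix.weights[nz]
        freqs = state.freqs
        rates6 = state.expanded_rates()

        # (n_cat, n_branch) scaled branch lengths -> (n_cat, n_nodes, 4, 4)
        scaled = np.multiply.outer(nz_rates, lengths)
        P = _transition_matrices(rates6, freqs, scaled)

        n_pat = self.patterns.n_patterns
        n_cat = len(nz_rates)
        partial: List[Optional[np.ndarray]] = [None] * tree.n_nodes
        scale_log = np.zeros(n_pat)
        for node in tree.postorder:
            if not tree.children[node]:
                leaf = self._leaf_partials[node]  # (n_pat, 4)
                partial[node] = np.broadcast_to(leaf, (n_cat, n_pat, 4))
                continue
            acc = np.ones((n_cat, n_pat, 4))
            for ch in tree.children[node]:
                down = np.einsum("cij,cpj->cpi", P[:, ch], partial[ch])
                acc = acc * down
                partial[ch] = None
            if node != tree.root:
                mx = acc.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                acc /= mx[None, :, None]
                scale_log += np.log(mx)
            partial[node] = acc

        root = partial[tree.root]
        site_lik = np.einsum("cpi,i->cp", root, freqs)  # (n_cat, n_pat)
        mixed = nz_weights @ site_lik  # (n_pat,)
        if np.any(mixed <= 0) and not state.has_inv:
            bad = np.flatnonzero(mixed <= 0)
            raise ArithmeticError(f"non-positive pattern likelihood at patterns {bad[:5]}")
        with np.errstate(divide="ignore"):
            log_pat = np.log(mixed) + scale_log
        if state.has_inv:
            inv = state.p_inv * (self._inv_mask @ freqs)  # (n_pat,)
            with np.errstate(divide="ignore"):
                log_pat = np.logaddexp(log_pat, np.log(inv, out=np.full_like(inv, -np.inf), where=inv > 0))
        total = float(self._counts @ log_pat)
        if not np.isfinite(total):
            raise ArithmeticError(
                f"non-finite log-likelihood (state={state!r}); "
                "check for patterns incompatible with the invariable category"
            )
        return total


def pruning_log_likelihood(tree: PhyloTree, pt: PatternTable, state: SiteModelState) -> float:
    """One-shot pruning log-likelihood (builds a TreeLikelihood internally)."""
    return TreeLikelihood(tree, pt).log_likelihood(state)


class DualTreeLikelihood:
    """Likelihood front-end with one cache per category configuration.

    The sampler toggles gamma rate heterogeneity on and off; the 1-category
    and the k-category evaluations are cached independently (keyed by the
    state components each depends on), so a toggle leaves the other
    configuration's cache intact and toggling back is a cache hit.
    """

    def __init__(self, tree: PhyloTree, patterns: PatternTable):
        self._engine = TreeLikelihood(tree, patterns)
        self._cache: Dict[bool, Optional[Tuple[tuple, float]]] = {False: None, True: None}
        self.n_evaluations = 0

    @staticmethod
    def _key(state: SiteModelState) -> tuple:
        key = (
            state.model.code,
            state.group_rates.tobytes(),
            state.freqs.tobytes(),
            state.has_inv,
            state.p_inv if state.has_inv else 0.0,
        )
        if state.has_gamma:
            key += (state.alpha, state.k)
        return key

    def log_likelihood(self, state: SiteModelState, blen: Optional[np.ndarray] = None) -> float:
        if blen is not None:  # height-sampling path: no caching across trees
            self.n_evaluations += 1
            return self._engine.log_likelihood(state, blen=blen)
        slot = bool(state.has_gamma)
        key = self._key(state)
        cached = self._cache[slot]
        if cached is not None and cached[0] == key:
            return cached[1]
        value = self._engine.log_likelihood(state)
        self.n_evaluations += 1
        self._cache[slot] = (key, value)
        return value


class ConstantLikelihood:
    """Likelihood stub returning 0.0 always — turns the sampler into a prior sampler."""

    def log_likelihood(self, state: SiteModelState, blen: Optional[np.ndarray] = None) -> float:
        return 0.0
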