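"""Pattern compression and pruning likelihood against independent oracles."""

import math

import numpy as np
import pytest

from oracles import brute_log_likelihood

from modeljump.likelihood import (
    ConstantLikelihood,
    DualTreeLikelihood,
    PhyloTree,
    TreeLikelihood,
    compress_patterns,
    pruning_log_likelihood,
)
from modeljump.model_space import ModelId
from modeljump.priors import PriorConfig, sample_prior
from modeljump.site_model import SiteModelState

JC = ModelId.from_string("111111")


def _random_alignment(rng, taxa=("A", "B", "C"), length=6, alphabet="ACGT"):
    return {t: "".join(rng.choice(list(alphabet), size=length)) for t in taxa}


class TestCompression:
    def test_identical_sequences(self):
        pt = compress_patterns({"x": "AAAA", "y": "AAAA", "z": "AAAA"})
        assert pt.n_patterns == 1
        assert pt.counts.tolist() == [4]
        assert pt.invariant_compat(0) == ("A",)

    def test_ambiguity_resolution(self):
        pt = compress_patterns({"x": "A", "y": "N", "z": "A"})
        assert pt.invariant_compat(0) == ("A",)
        pt = compress_patterns({"x": "R", "y": "N", "z": "G"})
        assert pt.invariant_compat(0) == ("G",)

    def test_counts_sum_and_pattern_bound(self, rng):
        aln = _random_alignment(rng, length=500)
        pt = compress_patterns(aln)
        assert pt.n_sites == 500
        assert pt.n_patterns <= 64  # at most 4^3 unambiguous three-taxon patterns

    @pytest.mark.parametrize(
        "aln",
        [
            {},
            {"x": "AC", "y": "A"},
            {"x": "AJ", "y": "AC"},
        ],
    )
    def test_bad_alignments_raise(self, aln):
        with pytest.raises(ValueError):
            compress_patterns(aln)


class TestPruning:
    def test_jc_two_taxon_closed_form(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.15);")
        d = 0.25
        same = 0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3))
        diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * d / 3))
        state = SiteModelState(JC, [1.0])
        ll = pruning_log_likelihood(tree, compress_patterns({"A": "ACG", "B": "AGG"}), state)
        assert ll == pytest.approx(2 * math.log(same) + math.log(diff), abs=1e-12)

    def test_zero_branch_lengths_constant_pattern(self):
        tree = PhyloTree.from_newick("(A:0.0,(B:0.0,C:0.0):0.0);")
        state = SiteModelState(JC, [1.0], has_est_freqs=1, freqs=[0.4, 0.3, 0.2, 0.1])
        ll = pruning_log_likelihood(tree, compress_patterns({"A": "A", "B": "A", "C": "A"}), state)
        assert ll == pytest.approx(math.log(0.4), abs=1e-10)

    @pytest.mark.parametrize("force", [
        {"has_gamma": 0, "has_inv": 0},
        {"has_gamma": 1, "has_inv": 0},
        {"has_gamma": 0, "has_inv": 1},
        {"has_gamma": 1, "has_inv": 1},
    ])
    def test_matches_brute_force_enumeration(self, rng, tstv_set, force):
        """Pruning equals explicit summation over internal states to 1e-10."""
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        aln = _random_alignment(rng, length=6, alphabet="ACGTN-")
        state = sample_prior(PriorConfig(), tstv_set, rng, force=force)
        ours = pruning_log_likelihood(tree, compress_patterns(aln), state)
        assert ours == pytest.approx(brute_log_likelihood(tree, aln, state), abs=1e-10)

    def test_invariant_shortcut_is_exact(self, rng, tstv_set):
        """The rate-0 category contributes p_inv * sum(pi over compatible bases)."""
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        aln = {"A": "G", "B": "G", "C": "N"}
        state = sample_prior(PriorConfig(), tstv_set, rng, force={"has_inv": 1, "has_gamma": 0})
        ll = pruning_log_likelihood(tree, compress_patterns(aln), state)
        # explicit zero-rate-category evaluation:
        #   p_inv * pi_G + (1 - p_inv) * L(plain model on tree scaled by 1/(1-p_inv))
        p = state.p_inv
        plain = state.copy()
        plain.has_inv = 0
        scaled = PhyloTree(tree.taxa, tree.parent, tree.blen / (1.0 - p), tree.children)
        explicit = p * state.freqs[2] + (1.0 - p) * math.exp(
            brute_log_likelihood(scaled, aln, plain)
        )
        assert ll == pytest.approx(math.log(explicit), abs=1e-10)
        # a pattern incompatible with any constant column gets no contribution
        aln2 = {"A": "G", "B": "T", "C": "N"}
        ll2 = pruning_log_likelihood(tree, compress_patterns(aln2), state)
        explicit2 = (1.0 - p) * math.exp(brute_log_likelihood(scaled, aln2, plain))
        assert ll2 == pytest.approx(math.log(explicit2), abs=1e-10)

    def test_compression_and_taxon_order_invariance(self, rng, tstv_set):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        aln = _random_alignment(rng, length=40)
        state = sample_prior(PriorConfig(), tstv_set, rng)
        ll = pruning_log_likelihood(tree, compress_patterns(aln), state)
        # site-by-site evaluation (no pooling of repeated columns)
        per_site = 0.0
        for i in range(40):
            col = {t: aln[t][i] for t in aln}
            per_site += pruning_log_likelihood(tree, compress_patterns(col), state)
        assert ll == pytest.approx(per_site, rel=1e-12)
        shuffled = {t: aln[t] for t in ["C", "A", "B"]}
        assert pruning_log_likelihood(tree, compress_patterns(shuffled), state) == pytest.approx(
            ll, rel=1e-12
        )

    def test_pinv_to_zero_limit(self, rng, tstv_set):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        pt = compress_patterns(_random_alignment(rng, length=30))
        state = sample_prior(PriorConfig(), tstv_set, rng, force={"has_inv": 1})
        base = state.copy()
        base.has_inv = 0
        ll0 = pruning_log_likelihood(tree, pt, base)
        state.p_inv = 1e-12
        assert pruning_log_likelihood(tree, pt, state) == pytest.approx(ll0, abs=1e-8)


class TestDualLikelihood:
    def test_toggle_returns_cached_bit_identical(self, rng, tstv_set):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        pt = compress_patterns(_random_alignment(rng, length=50))
        dual = DualTreeLikelihood(tree, pt)
        state = sample_prior(PriorConfig(), tstv_set, rng, force={"has_gamma": 0})
        v_plain = dual.log_likelihood(state)
        state_g = state.copy()
        state_g.has_gamma = 1
        v_gamma = dual.log_likelihood(state_g)
        evals = dual.n_evaluations
        # toggling back and forth hits the per-configuration caches
        assert dual.log_likelihood(state) == v_plain
        assert dual.log_likelihood(state_g) == v_gamma
        assert dual.n_evaluations == evals
        # fresh engines agree exactly
        engine = TreeLikelihood(tree, pt)
        assert engine.log_likelihood(state) == v_plain
        assert engine.log_likelihood(state_g) == v_gamma

    def test_cached_equals_uncached_over_random_states(self, rng, tstv_set):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        pt = compress_patterns(_random_alignment(rng, length=50))
        dual = DualTreeLikelihood(tree, pt)
        engine = TreeLikelihood(tree, pt)
        for _ in range(100):
            state = sample_prior(PriorConfig(), tstv_set, rng)
            assert dual.log_likelihood(state) == pytest.approx(
                engine.log_likelihood(state), abs=1e-12
            )

    def test_constant_mode(self, rng, tstv_set):
        state = sample_prior(PriorConfig(), tstv_set, rng)
        assert ConstantLikelihood().log_likelihood(state) == 0.0


class TestPhyloTree:
    def test_fixed_tree_geometry(self):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        assert sorted(tree.taxa) == ["A", "B", "C"]
        heights = tree.node_heights()
        assert heights[tree.root] == pytest.approx(0.2)
        assert tree.blen[: tree.n_leaves].tolist() == pytest.approx([0.2, 0.15, 0.15])

    def test_newick_roundtrip(self):
        newick = "(A:0.2,(B:0.15,C:0.15):0.05);"
        tree = PhyloTree.from_newick(newick)
        again = PhyloTree.from_newick(tree.to_newick())
        assert again.taxa == tree.taxa
        np.testing.assert_allclose(again.blen, tree.blen)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(A:0.2,B:-0.1);")
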