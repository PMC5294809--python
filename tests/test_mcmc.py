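"""Proposal algebra, Jacobians, detailed balance, chain reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from modeljump.likelihood import PhyloTree, TreeLikelihood, compress_patterns
from modeljump.mcmc import (
    ChainConfig,
    merge_rates,
    propose_gamma_birth_death,
    propose_inv_birth_death,
    propose_freq_flip,
    propose_freq_walk,
    propose_merge,
    propose_rate_exchange,
    propose_scale,
    propose_split,
    run_chain,
    split_rates,
)
from modeljump.model_space import ModelId, ModelSet
from modeljump.priors import PriorConfig, log_prior, sample_prior
from modeljump.site_model import SiteModelState


class TestSplitMergeAlgebra:
    def test_split_conserves_rate_mass(self):
        r_i, r_j = split_rates(1.2, 0.7, n_i=2, n_j=3)
        assert 2 * r_i + 3 * r_j == pytest.approx(5 * 1.2)

    def test_merge_is_weighted_mean(self):
        assert merge_rates(2.0, 0.5, n_i=2, n_j=4) == pytest.approx(1.0)

    def test_merge_inverts_split(self):
        r, u = 0.9, -0.35
        r_i, r_j = split_rates(r, u, 1, 4)
        assert merge_rates(r_i, r_j, 1, 4) == pytest.approx(r, abs=1e-14)

    @pytest.mark.parametrize("n_i,n_j", [(1, 1), (1, 4), (2, 3), (2, 2)])
    def test_split_jacobian_matches_finite_difference(self, n_i, n_j):
        """|det d(r_i,r_j)/d(r,u)| equals (n_i+n_j)/(n_i n_j) to 1e-6."""
        r, u = 1.3, 0.21
        h = 1e-7
        J = np.empty((2, 2))
        for col, (dr, du) in enumerate([(h, 0.0), (0.0, h)]):
            hi = split_rates(r + dr, u + du, n_i, n_j)
            lo = split_rates(r - dr, u - du, n_i, n_j)
            J[:, col] = (np.array(hi) - np.array(lo)) / (2 * h)
        assert abs(np.linalg.det(J)) == pytest.approx((n_i + n_j) / (n_i * n_j), abs=1e-6)

    def test_proposals_preserve_sum_and_are_reversible(self, tstv_set, rng):
        cfg = PriorConfig()
        for _ in range(200):
            state = sample_prior(cfg, tstv_set, rng)
            out = propose_split(state, tstv_set.graph, rng)
            if out.self_move or not out.valid:
                continue
            s2 = out.proposed_state
            assert s2.rate_sum() == pytest.approx(6.0, abs=1e-10)
            assert s2.model.dof == state.model.dof + 1
            # the matching merge recovers the original state exactly
            back = None
            info = tstv_set.graph.split_info(state.model, s2.model)
            r = merge_rates(
                s2.group_rates[info.child_i],
                s2.group_rates[info.child_j],
                s2.model.group_sizes[info.child_i],
                s2.model.group_sizes[info.child_j],
            )
            assert r == pytest.approx(state.group_rates[info.parent_group], abs=1e-12)

    def test_boundary_models_propose_self(self, tstv_set, rng):
        gtr = SiteModelState(ModelId.from_string("123456"), np.full(6, 1.0))
        out = propose_split(gtr, tstv_set.graph, rng)
        assert out.self_move and out.log_hastings == 0.0
        jc = SiteModelState(ModelId.from_string("111111"), [1.0])
        out = propose_merge(jc, tstv_set.graph, rng)
        assert out.self_move and out.log_hastings == 0.0

    def test_split_hastings_antisymmetric_with_merge(self, tstv_set, rng):
        """log q-ratio of a split equals minus that of the matching merge."""
        cfg = PriorConfig()
        found = 0
        for _ in range(100):
            state = sample_prior(cfg, tstv_set, rng)
            out = propose_split(state, tstv_set.graph, rng)
            if out.self_move:
                continue
            s2 = out.proposed_state
            parents = tstv_set.graph.merge_candidates(s2.model)
            info = tstv_set.graph.split_info(state.model, s2.model)
            n = s2.model.group_sizes[info.child_i] + s2.model.group_sizes[info.child_j]
            s = n * float(state.group_rates[info.parent_group])
            expected = (
                math.log(s)
                + math.log(len(tstv_set.graph.split_candidates(state.model)))
                - math.log(len(parents))
            )
            assert out.log_hastings == pytest.approx(expected, abs=1e-12)
            found += 1
        assert found > 20


class TestRateExchange:
    def test_sum_preserved_and_failure_rule(self, tstv_set, rng):
        cfg = PriorConfig()
        n_valid = n_invalid = 0
        for _ in range(300):
            state = sample_prior(cfg, tstv_set, rng)
            out = propose_rate_exchange(state, delta=1.0, rng=rng)
            if out.self_move:
                assert state.model.n_groups == 1
                continue
            if out.valid:
                n_valid += 1
                assert out.proposed_state.rate_sum() == pytest.approx(6.0, abs=1e-10)
                assert out.log_hastings == 0.0
                assert np.all(out.proposed_state.group_rates > 0)
            else:
                n_invalid += 1
                assert out.proposed_state is state  # automatic reject, state untouched
        assert n_valid > 50 and n_invalid > 5

    def test_zero_transfer_is_identity(self, tstv_set):
        state = SiteModelState(ModelId.from_string("121121"), [1.0, 1.0])

        class _ZeroRng:
            def integers(self, *a, **k):
                return 0

            def uniform(self, lo, hi):
                return 0.0

        out = propose_rate_exchange(state, delta=1.0, rng=_ZeroRng())
        np.testing.assert_allclose(out.proposed_state.group_rates, state.group_rates)


class TestIndicatorProposals:
    def test_birth_death_cancellation(self, tstv_set, rng):
        """With the prior as birth density, prior x Hastings reduces to the
        indicator-prior ratio (which is 0 in log for a half-half prior)."""
        cfg = PriorConfig()
        state = sample_prior(cfg, tstv_set, rng, force={"has_gamma": 0})
        out = propose_gamma_birth_death(state, cfg, rng)
        assert out.proposed_state.has_gamma == 1
        log_r = (
            log_prior(out.proposed_state, cfg, tstv_set)
            - log_prior(state, cfg, tstv_set)
            + out.log_hastings
        )
        assert log_r == pytest.approx(0.0, abs=1e-12)
        # immediate death restores the original log prior exactly
        back = propose_gamma_birth_death(out.proposed_state, cfg, rng)
        assert back.proposed_state.has_gamma == 0
        assert log_prior(back.proposed_state, cfg, tstv_set) == pytest.approx(
            log_prior(state, cfg, tstv_set), abs=1e-12
        )

    def test_inv_and_freq_flip_cancellation(self, tstv_set, rng):
        cfg = PriorConfig()
        state = sample_prior(cfg, tstv_set, rng, force={"has_inv": 0, "has_est_freqs": 0})
        for proposer in (propose_inv_birth_death, propose_freq_flip):
            out = proposer(state, cfg, rng)
            log_r = (
                log_prior(out.proposed_state, cfg, tstv_set)
                - log_prior(state, cfg, tstv_set)
                + out.log_hastings
            )
            assert log_r == pytest.approx(0.0, abs=1e-12)

    def test_flip_to_equal_resets_frequencies(self, tstv_set, rng):
        cfg = PriorConfig()
        state = sample_prior(cfg, tstv_set, rng, force={"has_est_freqs": 1})
        out = propose_freq_flip(state, cfg, rng)
        np.testing.assert_allclose(out.proposed_state.freqs, 0.25)

    def test_freq_walk_stays_on_simplex(self, tstv_set, rng):
        cfg = PriorConfig()
        state = sample_prior(cfg, tstv_set, rng, force={"has_est_freqs": 1})
        for _ in range(100):
            out = propose_freq_walk(state, rng, delta=0.1)
            if out.valid:
                f = out.proposed_state.freqs
                assert f.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(f > 0)

    def test_scale_kernel(self, rng):
        for _ in range(100):
            v, log_h = propose_scale(2.5, 0.75, rng)
            assert v > 0
            s = v / 2.5
            assert 0.75 <= s <= 1 / 0.75
            assert log_h == pytest.approx(-math.log(s))
        with pytest.raises(ValueError):
            propose_scale(1.0, 1.5, rng)


class TestChain:
    def _toy_data(self):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        aln = {"A": "ACGTAG", "B": "ACGTGG", "C": "ACTTAG"}
        return tree, compress_patterns(aln)

    def test_identical_seeds_identical_traces(self, tstv_set):
        tree, pt = self._toy_data()
        cfg = ChainConfig(chain_length=2000, log_every=50, seed=42)
        prior = PriorConfig()
        t1 = run_chain(pt, tree, tstv_set, prior, cfg)
        t2 = run_chain(pt, tree, tstv_set, prior, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_trace_rows_satisfy_rate_sum(self, tstv_set):
        tree, pt = self._toy_data()
        cfg = ChainConfig(chain_length=3000, log_every=20, seed=9)
        trace = run_chain(pt, tree, tstv_set, PriorConfig(), cfg)
        rates = trace[["rateAC", "rateAG", "rateAT", "rateCG", "rateCT", "rateGT"]].to_numpy()
        np.testing.assert_allclose(rates.sum(axis=1), 6.0, atol=1e-9)
        assert set(trace["hasEqualFreqs"].unique()) <= {0, 1}

    def test_two_model_posterior_matches_enumeration(self):
        """Chain model frequencies vs the exact marginal likelihoods of a
        two-model space, computed by quadrature over the rate coordinate."""
        jc = ModelId.from_string("111111")
        hky = ModelId.from_string("121121")
        mset = ModelSet([jc, hky], kind="custom")
        tree, pt = self._toy_data()
        engine = TreeLikelihood(tree, pt)

        def lik_hky(s_ts: float) -> float:
            # group rates (tv, ts) from the transition mass s_ts
            state = SiteModelState(hky, [(6.0 - s_ts) / 4.0, s_ts / 2.0])
            return math.exp(engine.log_likelihood(state))

        m_jc = math.exp(engine.log_likelihood(SiteModelState(jc, [1.0])))
        m_hky, err = quad(lambda s: lik_hky(s) / 6.0, 1e-9, 6.0 - 1e-9, limit=200)
        exact_p_hky = m_hky / (m_hky + m_jc)

        cfg = ChainConfig(
            chain_length=150_000,
            log_every=10,
            seed=2718,
            operator_weights={
                "gamma_toggle": 0.0, "inv_toggle": 0.0, "alpha_scale": 0.0,
                "pinv_walk": 0.0, "freq_flip": 0.0, "freq_walk": 0.0,
            },
        )
        prior = PriorConfig(rate_prior="flat_dirichlet", model_prior="uniform_models")
        init = SiteModelState(jc, [1.0])
        trace = run_chain(pt, tree, mset, prior, cfg, init_state=init)
        trace = trace.iloc[len(trace) // 10 :]
        p_hky = float((trace["model"] == "121121").mean())
        # Monte-Carlo tolerance: generous 4-sigma band for a correlated chain
        se = math.sqrt(exact_p_hky * (1 - exact_p_hky) / (len(trace) / 20))
        assert p_hky == pytest.approx(exact_p_hky, abs=max(4 * se, 0.02))

    def test_prior_chain_short_smoke(self, tstv_set):
        cfg = ChainConfig(chain_length=30_000, log_every=10, seed=3)
        trace = run_chain(None, None, tstv_set, PriorConfig(), cfg)
        tr = trace.iloc[len(trace) // 10 :]
        assert tr["hasGammaRates"].mean() == pytest.approx(0.5, abs=0.05)
        assert tr["model"].nunique() == 31

    def test_bad_initial_state_raises(self, tstv_set):
        tree, pt = self._toy_data()
        bad = SiteModelState(ModelId.from_string("111111"), [1.0], has_inv=1, p_inv=0.999999)
        bad.p_inv = 1.5  # outside support
        with pytest.raises((RuntimeError, ValueError)):
            run_chain(pt, tree, tstv_set, PriorConfig(), ChainConfig(chain_length=100, seed=1), init_state=bad)


class TestHeightSampling:
    def test_strict_clock_heights_smoke(self, tstv_set):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.15,C:0.15):0.05);")
        pt = compress_patterns({"A": "ACGTAG", "B": "ACGTGG", "C": "ACTTAG"})
        cfg = ChainConfig(chain_length=2000, log_every=100, seed=5, sample_tree_heights=True)
        t1 = run_chain(pt, tree, tstv_set, PriorConfig(), cfg)
        t2 = run_chain(pt, tree, tstv_set, PriorConfig(), cfg)
        pd.testing.assert_frame_equal(t1, t2)
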