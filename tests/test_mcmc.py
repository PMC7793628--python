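"""Sampler arithmetic, operators, diagnostics and consensus trees."""

import math

import numpy as np
import pandas as pd
import pytest

from dynhom.mcmc import (HomologyFlipOperator, McmcConfig, RateDeltaExchange,
                         TreeOperator, _propose_exchange,
                         _propose_wilson_balding, burnin_discard,
                         consensus_newick, default_operators, ess,
                         majority_rule_consensus, n_samples,
                         retained_sample_count, run_mcmc)
from dynhom.pipeline import RunConfig, compute_partition_scheme, \
    make_model_state
from dynhom.simulate import make_fig2_fixture
from dynhom.tree import TimeTree


class TestSampleCounting:
    def test_study_settings_yield_1801(self):
        assert n_samples(800_000_000, 400_000) == 2001
        assert burnin_discard(2001, 0.10) == 200
        assert retained_sample_count(800_000_000, 400_000, 0.10) == 1801

    def test_small_chain_counts_initial_state(self):
        assert n_samples(1000, 100) == 11
        assert retained_sample_count(1000, 100, 0.0) == 11

    def test_ten_percent_of_eleven_retains_ten(self):
        assert retained_sample_count(1000, 100, 0.10) == 10

    def test_indivisible_chain_rejected(self):
        with pytest.raises(ValueError):
            n_samples(1001, 100)


def _small_state(seed=1, which=2, **kwargs):
    fixed, block, _ = make_fig2_fixture(which)
    part = compute_partition_scheme(fixed, [block])
    cfg = RunConfig(chain_length=2000, sample_every=100, seed=seed, rho=1.0)
    return make_model_state(fixed, [block], part.scheme, cfg, **kwargs)


class TestDeterminism:
    def test_same_seed_identical_logs(self):
        results = []
        for _ in range(2):
            state = _small_state(seed=5)
            res = run_mcmc(state, McmcConfig(chain_length=2000,
                                             sample_every=100, seed=5),
                           keep_tree_objects=False)
            results.append(res)
        pd.testing.assert_frame_equal(results[0].trace, results[1].trace)
        assert results[0].trees == results[1].trees

    def test_audit_mode_detects_no_cache_drift(self):
        state = _small_state(seed=2)
        run_mcmc(state, McmcConfig(chain_length=2000, sample_every=200,
                                   seed=2, audit_every=250),
                 keep_tree_objects=False)


class TestOperators:
    def test_homology_flip_two_states_always_flips(self, rng):
        state = _small_state()
        op = HomologyFlipOperator()
        for _ in range(20):
            before = state.homology[0]
            op._undo = None
            assert op.propose(state, rng) == 0.0
            assert state.homology[0] != before

    def test_flip_visits_all_states_uniformly(self, rng):
        # on the flat prior every flip is accepted, so a two-state chain
        # alternates deterministically: occupancy is exactly uniform
        state = _small_state(sample_from_prior=True,
                             include_tree_prior=False)
        res = run_mcmc(state, McmcConfig(chain_length=2000, sample_every=1,
                                         seed=3, tune=False),
                       operators=[HomologyFlipOperator()],
                       keep_tree_objects=False)
        freq = (res.trace["h_0"] == 1).mean()
        assert 0.45 < freq < 0.55

    def test_rate_delta_exchange_conserves_weighted_mean(self, rng):
        from dynhom.matrix import partition_characters
        from dynhom.mk import MkPartitionModel

        state = _small_state()
        # install a two-partition model (the didactic fixture itself
        # collapses to one partition)
        scheme = partition_characters([2] * 4 + [3] * 4, [0] * 8)
        state.scheme = scheme
        state.partition_model = MkPartitionModel.flat(scheme)
        model = state.partition_model
        model.rates[:] = [1.6, 0.4]
        op = RateDeltaExchange()
        before = model.weighted_mean()
        for _ in range(50):
            op._undo = None
            op.propose(state, rng)
            assert model.weighted_mean() == pytest.approx(before, abs=1e-9)

    def test_wilson_balding_preserves_tree_validity(self, rng):
        state = _small_state()
        for _ in range(200):
            out = _propose_wilson_balding(state, rng)
            if out is not None:
                state.tree.validate()
                # keep the move half the time, otherwise undo
                if rng.random() < 0.5:
                    out[1]()
                state.tree.validate()

    def test_exchange_preserves_tree_validity(self, rng):
        state = _small_state()
        for _ in range(200):
            out = _propose_exchange(state, rng)
            if out is not None:
                state.tree.validate()
                out[1]()
                state.tree.validate()

    def test_joint_operator_changes_topology_and_homology(self, rng):
        state = _small_state()
        op = TreeOperator("joint", _propose_wilson_balding,
                          with_homology=True)
        changed_both = False
        for _ in range(300):
            before_h = list(state.homology)
            before_t = state.tree.newick(include_ages=False)
            op._undo = None
            if op.propose(state, rng) is None:
                continue
            after_h = list(state.homology)
            after_t = state.tree.newick(include_ages=False)
            if after_h != before_h and after_t != before_t:
                changed_both = True
                break
            op.undo()
        assert changed_both

    def test_default_schedule_covers_all_parameter_kinds(self):
        state = _small_state()
        names = {op.name for op in default_operators(state)}
        for expected in ("birth_scale", "clock_rate_scale",
                         "node_age_uniform", "sa_wilson_balding",
                         "leaf_sa_jump", "homology_flip",
                         "homology_sa_wilson_balding"):
            assert expected in names


class TestEss:
    def test_iid_draws(self, rng):
        x = rng.normal(size=1000)
        assert ess(x) == pytest.approx(1000, rel=0.15)

    def test_ar1_known_autocorrelation(self, rng):
        rho = 0.9
        n = 20_000
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + noise[i]
        expected = n * (1 - rho) / (1 + rho)
        assert ess(x) == pytest.approx(expected, rel=0.3)

    def test_alternating_sequence_clamped(self):
        x = np.array([0.0, 1.0] * 200)
        assert ess(x) <= 400

    def test_constant_trace_flagged(self):
        assert math.isnan(ess(np.ones(100)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestConsensus:
    def _trees(self, newicks):
        return [TimeTree.from_newick(n) for n in newicks]

    def test_identical_trees_full_frequencies(self):
        trees = self._trees(["((A:1,B:1):1,C:2);"] * 4)
        cons = majority_rule_consensus(trees)
        assert cons.frequency == 1.0
        ab = cons.children[0] if len(cons.children[0].clade) == 2 else \
            cons.children[1]
        assert ab.clade == frozenset({"A", "B"})
        assert ab.frequency == 1.0
        assert ab.mean_age == pytest.approx(1.0)

    def test_two_of_three_trees_clade_retained(self):
        trees = self._trees([
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,B:1):2,(C:1,D:1):2);",
            "(((A:1,C:1):1,B:2):1,D:3);",
        ])
        cons = majority_rule_consensus(trees)
        clades = {}

        def walk(nd):
            clades[nd.clade] = nd
            for c in nd.children:
                walk(c)

        walk(cons)
        ab = clades[frozenset({"A", "B"})]
        assert ab.frequency == pytest.approx(2 / 3)
        # both trees containing {A,B} place its MRCA at age 1
        assert ab.mean_age == pytest.approx(1.0)

    def test_exactly_half_excluded(self):
        trees = self._trees([
            "((A:1,B:1):1,(C:1,D:1):1);",
            "(((A:1,C:1):1,B:2):1,D:3);",
        ])
        cons = majority_rule_consensus(trees)
        found = set()

        def walk(nd):
            found.add(nd.clade)
            for c in nd.children:
                walk(c)

        walk(cons)
        assert frozenset({"A", "B"}) not in found
        assert frozenset({"A", "C"}) not in found

    def test_tip_set_mismatch_rejected(self):
        trees = self._trees(["(A:1,B:1);", "(A:1,C:1);"])
        with pytest.raises(ValueError):
            majority_rule_consensus(trees)

    def test_newick_rendering(self):
        trees = self._trees(["((A:1,B:1):1,C:2);"] * 2)
        text = consensus_newick(majority_rule_consensus(trees))
        assert "A" in text and text.endswith(";")


class TestPriorSampling:
    def test_scalar_priors_recovered_without_tree_coupling(self):
        """With the likelihood off and the tree held fixed, MH sampling
        reproduces each parameter's own prior."""
        from scipy import stats

        from dynhom.mcmc import OriginOperator, ScaleOperator, SiteAgeOperator

        state = _small_state(sample_from_prior=True,
                             include_tree_prior=False)
        ops = [
            ScaleOperator("birth_scale", lambda s: s.fbd.birth,
                          lambda s, v: setattr(s.fbd, "birth", v),
                          tuning=2.0),
            HomologyFlipOperator(),
        ]
        res = run_mcmc(state, McmcConfig(chain_length=40_000, sample_every=20,
                                         seed=11, tune=False),
                       operators=ops, keep_tree_objects=False)
        births = res.retained()["birth"].to_numpy()
        dist = state.priors.birth_dist()
        ks = stats.kstest(births[::10], dist.cdf)
        assert ks.pvalue > 0.01
        h = res.retained()["h_0"].to_numpy()
        assert 0.4 < (h == 1).mean() < 0.6
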