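"""Mk transition probabilities and pruning likelihood vs enumeration."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from dynhom.matrix import MISSING, MorphMatrix
from dynhom.mk import MkLikelihood, MkPartitionModel, mk_transition_prob
from dynhom.tree import Node, TimeTree
from tests.conftest import random_matrix, random_time_tree


class TestTransitionProb:
    def test_zero_distance_identity(self):
        assert np.allclose(mk_transition_prob(4, 0.0), np.eye(4))

    def test_stationary_limit(self):
        P = mk_transition_prob(3, 500.0)
        assert np.allclose(P, np.full((3, 3), 1 / 3), atol=1e-12)

    @pytest.mark.parametrize("k,d", [(2, 0.1), (3, 0.3), (4, 1.7), (5, 0.01)])
    def test_matches_matrix_exponential(self, k, d):
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        assert np.allclose(mk_transition_prob(k, d), expm(Q * d), atol=1e-12)

    def test_rows_sum_to_one(self):
        P = mk_transition_prob(7, 0.42)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            mk_transition_prob(2, -0.1)


def brute_force_loglik(tree, matrix, rates, clock):
    """Exhaustive sum over all internal and ambiguous-tip assignments."""
    post = tree.postorder()
    total = 0.0
    for j in range(matrix.n_char):
        k = max(matrix.state_count(j), 2)
        alphabet = sorted(matrix.observed_states(j)) or [0, 1]
        internals = [nd for nd in post if nd.children]
        tipsets = {}
        for taxon, row in zip(matrix.taxa, matrix.cells):
            cell = row[j]
            if isinstance(cell, frozenset):
                ranks = {alphabet.index(s) for s in cell if s in alphabet}
                tipsets[taxon] = ranks or set(range(k))
            else:
                tipsets[taxon] = set(range(k))
        like = 0.0
        tips = tree.tips()
        for internal_states in itertools.product(range(k), repeat=len(internals)):
            base = {id(nd): s for nd, s in zip(internals, internal_states)}
            for tip_states in itertools.product(
                    *[sorted(tipsets[t.label]) for t in tips]):
                smap = dict(base)
                for nd, s in zip(tips, tip_states):
                    smap[id(nd)] = s
                p = 1.0 / k
                for nd in post:
                    if nd.parent is None:
                        continue
                    d = tree.branch_duration(nd) * clock * \
                        nd.rate_multiplier * rates[j]
                    P = mk_transition_prob(k, d)
                    p *= P[smap[id(nd.parent)], smap[id(nd)]]
                like += p
        total += math.log(like)
    return total


class TestPruning:
    def test_two_identical_tips_zero_branches(self):
        root = Node(age=0.0)
        a, b = Node("A", 0.0), Node("B", 0.0)
        root.children = [a, b]
        a.parent = b.parent = root
        tree = TimeTree(root)
        m = MorphMatrix(taxa=["A", "B"],
                        cells=[[frozenset({0})], [frozenset({0})]])
        assert MkLikelihood(m).loglik(tree) == pytest.approx(math.log(0.5))

    def test_all_missing_character_contributes_zero(self, rng):
        tree = random_time_tree(rng, ["A", "B", "C"])
        m = MorphMatrix(taxa=["A", "B", "C"], cells=[[MISSING]] * 3)
        assert MkLikelihood(m).loglik(tree) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 6))
            labels = [f"t{i}" for i in range(n)]
            tree = random_time_tree(rng, labels, max_tip_age=1.0)
            for nd in tree.postorder():
                nd.rate_multiplier = float(rng.uniform(0.5, 2.0))
            m = random_matrix(rng, n, int(rng.integers(1, 4)),
                              n_states=3, missing=0.25)
            rates = rng.uniform(0.3, 2.0, m.n_char)
            clock = float(rng.uniform(0.2, 1.5))
            ours = MkLikelihood(m, rates).loglik(tree, clock)
            oracle = brute_force_loglik(tree, m, rates, clock)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_invariant_under_rerooting(self, rng):
        # likelihood of a reversible model with uniform root frequencies
        # does not depend on root placement along a branch
        tree = TimeTree.from_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        m = random_matrix(rng, 4, 5, n_states=2)
        m.taxa[:] = ["A", "B", "C", "D"]
        base = MkLikelihood(m).loglik(tree)
        # same unrooted metric, root shifted along the internal edge
        alt = TimeTree.from_newick("((A:1,B:2):0.5,(C:1.5,D:0.5):2.5);")
        assert MkLikelihood(m).loglik(alt) == pytest.approx(base, rel=1e-10)

    def test_long_terminal_branch_reaches_stationarity(self):
        tree = TimeTree.from_newick("(A:1000,B:0.1);")
        m = MorphMatrix(taxa=["A", "B"],
                        cells=[[frozenset({0})], [frozenset({0})]])
        ll = MkLikelihood(m).loglik(tree)
        # tip A contributes the stationary 1/2; summing the root state out
        # over B's transition row gives exactly 1/2 * 1/2
        assert math.exp(ll) == pytest.approx(0.25, rel=1e-6)

    def test_per_character_likelihood_in_unit_interval(self, rng):
        m = random_matrix(rng, 4, 10, n_states=3)
        tree = random_time_tree(rng, m.taxa)
        ll = MkLikelihood(m).loglik(tree)
        assert ll <= 0.0

    def test_missing_tip_row_rejected(self, rng):
        tree = random_time_tree(rng, ["A", "B", "C"])
        m = random_matrix(rng, 3, 2)
        m.taxa[:] = ["A", "B", "X"]
        with pytest.raises(ValueError, match="X"):
            MkLikelihood(m).loglik(tree)


class TestPartitionModel:
    def test_weighted_mean_constraint_enforced(self):
        with pytest.raises(ValueError):
            MkPartitionModel(state_counts=[2, 2], rates=np.array([1.5, 1.5]),
                             weights=np.array([10.0, 30.0]))

    def test_valid_weighted_mean(self):
        m = MkPartitionModel(state_counts=[2, 2],
                             rates=np.array([1.6, 0.8]),
                             weights=np.array([10.0, 30.0]))
        assert m.weighted_mean() == pytest.approx(1.0)
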