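"""Tree prior (sampled-ancestor birth-death), clock and parameter priors."""

import math

import numpy as np
import pytest

from dynhom.priors import (FBDParams, FossilSite, InvalidDensityError,
                           PriorConfig, RelaxedClock, SiteAgeParams,
                           check_monophyly, fbd_log_density, lognormal,
                           lognormal_logpdf)
from dynhom.tree import Node, TimeTree


def _tree(newick):
    return TimeTree.from_newick(newick)


def birth_death_log_density(tree, birth, death, rho, origin):
    """Independent closed form for the extant-sample birth-death prior:
    oriented-tree density  p1(origin) * prod over bifurcations lambda*p1(x).
    """
    g = birth - death

    def p1(t):
        denom = rho * birth + (birth * (1 - rho) - death) * math.exp(-g * t)
        return rho * g ** 2 * math.exp(-g * t) / denom ** 2

    logp = math.log(p1(origin))
    for nd in tree.postorder():
        if nd.children:
            logp += math.log(birth) + math.log(p1(nd.age))
    return logp


class TestFbdDensity:
    def test_reduces_to_birth_death_when_sampling_vanishes(self):
        tree = _tree("((A:1,B:1):1,C:2);")  # all tips extant at age 0
        for rho in (0.3, 1.0):
            params = FBDParams(birth=1.2, death=0.4, sampling=1e-12,
                               origin=3.5, rho=rho)
            ours = fbd_log_density(tree, params)
            oracle = birth_death_log_density(tree, 1.2, 0.4, rho, 3.5)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_finite_for_fossil_trees(self):
        tree = TimeTree.from_newick("((A:1,B:2):1,(C:1,D:3):2);",
                                    tip_ages={"D": 1.0})
        assert min(t.age for t in tree.tips()) > 0
        params = FBDParams(birth=0.2, death=0.1, sampling=0.1,
                           origin=10.0, rho=0.0)
        val = fbd_log_density(tree, params)
        assert math.isfinite(val)

    def test_scaling_jacobian(self):
        """Scaling all ages by a and all rates by 1/a changes the density
        by a^-(number of time densities) exactly."""
        tree = TimeTree.from_newick("((A:1,B:2):1,(C:1,D:3):2);",
                                    tip_ages={"D": 1.0})
        params = FBDParams(birth=0.2, death=0.1, sampling=0.15,
                           origin=18.0, rho=0.0)
        base = fbd_log_density(tree, params)
        assert math.isfinite(base)
        a = 2.5
        scaled_tree = TimeTree.from_newick("((A:1,B:2):1,(C:1,D:3):2);",
                                           tip_ages={"D": 1.0})
        for nd in scaled_tree.postorder():
            nd.age *= a
        scaled = FBDParams(birth=0.2 / a, death=0.1 / a, sampling=0.15 / a,
                           origin=18.0 * a, rho=0.0)
        # time densities: 3 bifurcations + 4 fossil tips (0 sampled ancestors)
        n_density_terms = 3 + 4
        assert fbd_log_density(scaled_tree, scaled) == pytest.approx(
            base - n_density_terms * math.log(a), rel=1e-9)

    def test_sampled_ancestor_terms(self):
        # B sits as a zero-length attachment on the A lineage
        root = Node(age=3.0)
        att = Node(age=1.0)
        a = Node("A", 0.5)
        b = Node("B", 1.0)
        c = Node("C", 0.2)
        root.children = [att, c]
        att.parent = c.parent = root
        att.children = [a, b]
        a.parent = b.parent = att
        tree = TimeTree(root)
        assert tree.is_sampled_ancestor(b)
        params = FBDParams(birth=0.3, death=0.1, sampling=0.2,
                           origin=5.0, rho=0.0)
        with_sa = fbd_log_density(tree, params)
        assert math.isfinite(with_sa)
        # the same tree with the attachment lifted has one more
        # bifurcation term and a p0/q leaf term instead of a bare psi
        att.age = 1.5
        assert not tree.is_sampled_ancestor(b)
        lifted = fbd_log_density(tree, params)
        assert lifted != pytest.approx(with_sa)

    def test_tip_older_than_origin_rejected(self):
        tree = _tree("((A:1,B:2):1,(C:1,D:3):2);")
        params = FBDParams(birth=0.2, death=0.1, sampling=0.1,
                           origin=1.0, rho=0.0)
        with pytest.raises(InvalidDensityError):
            fbd_log_density(tree, params)

    def test_nonpositive_rates_rejected(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(InvalidDensityError):
            fbd_log_density(tree, FBDParams(birth=-1, death=0.1,
                                            sampling=0.1, origin=3))


class TestMonophyly:
    def test_single_taxon_always_true(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        assert check_monophyly(tree, [{"A"}])

    def test_non_clade_detected(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        assert not check_monophyly(tree, [{"A", "C"}])

    def test_nested_constraints(self):
        tree = _tree("(((A:1,B:1):1,C:2):1,D:3);")
        assert check_monophyly(tree, [{"A", "B"}, {"A", "B", "C"}])

    def test_unknown_taxon_raises(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(KeyError):
            check_monophyly(tree, [{"A", "Z"}])


class TestSiteAges:
    def test_out_of_bounds_is_rejected(self):
        sites = SiteAgeParams(sites=[FossilSite("s", 10.0, 20.0, ["A"])])
        sites.ages["s"] = 25.0
        assert sites.log_density() == -math.inf

    def test_uniform_density_value(self):
        sites = SiteAgeParams(sites=[FossilSite("s", 10.0, 20.0, ["A"])])
        assert sites.log_density() == pytest.approx(-math.log(10.0))

    def test_tip_age_lookup(self):
        sites = SiteAgeParams(sites=[FossilSite("s", 10.0, 20.0, ["A", "B"])])
        assert sites.tip_age("A") == pytest.approx(15.0)
        assert sites.tip_age("Z") is None


class TestParameterPriors:
    def test_lognormal_real_space_mean(self):
        dist = lognormal(real_space_mean=0.14, sigma=0.9)
        assert dist.mean() == pytest.approx(0.14, rel=1e-9)

    def test_lognormal_logpdf_matches_scipy(self):
        dist = lognormal(log_mean=-5.5, sigma=2.0)
        for x in (1e-4, 0.004, 0.1):
            assert lognormal_logpdf(x, -5.5, 2.0) == pytest.approx(
                float(dist.logpdf(x)), rel=1e-12)

    def test_clock_multiplier_prior_mean_one(self):
        clock = RelaxedClock(clock_rate=0.01, sigma=0.7)
        mu = -0.5 * 0.7 ** 2
        draws = np.random.default_rng(0).lognormal(mu, 0.7, 200_000)
        assert draws.mean() == pytest.approx(1.0, abs=0.01)
        assert math.isfinite(clock.multiplier_log_density(draws[:10]))

    def test_partition_rate_prior_at_mode(self):
        cfg = PriorConfig()
        # normal(1, 2) log-density at its mode
        expected = -math.log(2.0) - 0.5 * math.log(2 * math.pi)
        assert float(cfg.rate_dist().logpdf(1.0)) == pytest.approx(expected)
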