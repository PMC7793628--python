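"""Tree and parameter priors for tip-dated analyses.

The tree prior is the sampled-ancestor birth-death process (speciation
``lambda``, extinction ``mu``, through-time fossil sampling ``psi``,
extant sampling ``rho``, conditioned on the origin time).  Fossil tips
are assigned to fossil *sites*; every tip of a site shares the site's
age parameter, which carries a uniform prior over the site's
stratigraphic bounds.  The clock is an uncorrelated lognormal relaxed
clock: branch-rate multipliers are i.i.d. lognormal with real-space
mean one, multiplied by a global clock rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .tree import SA_EPS, TimeTree


class InvalidDensityError(ValueError):
    """Raised when a density is requested outside its domain."""


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def lognormal_logpdf(x: float, mu: float, sigma: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - mu) / sigma
    return -math.log(x * sigma) - _LOG_SQRT_2PI - 0.5 * z * z


def exponential_logpdf(x: float, mean: float) -> float:
    if x < 0:
        return -math.inf
    return -x / mean - math.log(mean)


def normal_logpdf(x: float, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return -math.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z


# ---------------------------------------------------------------------------
# Sampled-ancestor birth-death tree prior
# ---------------------------------------------------------------------------

@dataclass
class FBDParams:
    birth: float            # lambda, per-lineage speciation rate (1/Myr)
    death: float            # mu, extinction rate
    sampling: float         # psi, fossil-sampling rate
    origin: float           # origin time (Ma before present), > root age
    rho: float = 0.0        # extant sampling probability (0 for all-fossil)

    def validate(self) -> None:
        if self.birth <= 0 or self.death <= 0 or self.sampling < 0:
            raise InvalidDensityError("birth/death rates must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidDensityError("rho must lie in [0, 1]")
        if self.origin <= 0:
            raise InvalidDensityError("origin must be positive")


def _c1_c2(p: FBDParams) -> Tuple[float, float]:
    c1 = math.sqrt((p.birth - p.death - p.sampling) ** 2
                   + 4.0 * p.birth * p.sampling)
    if c1 == 0.0:
        raise InvalidDensityError("degenerate rates (c1 = 0)")
    c2 = -(p.birth - p.death - 2.0 * p.birth * p.rho - p.sampling) / c1
    return c1, c2


def _log_q(t: float, c1: float, c2: float) -> float:
    # q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1-c2) + (1+c2))^2
    emt = math.exp(-c1 * t)
    denom = emt * (1.0 - c2) + (1.0 + c2)
    if denom <= 0:
        raise InvalidDensityError("q(t) undefined for these rates")
    return math.log(4.0) - c1 * t - 2.0 * math.log(denom)


def _p0(t: float, p: FBDParams, c1: float, c2: float) -> float:
    emt = math.exp(-c1 * t)
    frac = (emt * (1.0 - c2) - (1.0 + c2)) / (emt * (1.0 - c2) + (1.0 + c2))
    return (p.birth + p.death + p.sampling + c1 * frac) / (2.0 * p.birth)


def fbd_log_density(tree: TimeTree, params: FBDParams,
                    eps: float = SA_EPS) -> float:
    """Log prior density of a dated SA tree under the FBD process.

    Factorisation per event: origin-to-root stem and every observed
    bifurcation at time x contribute ``q(x)`` (bifurcations additionally
    ``lambda``); a fossil leaf at y contributes ``psi p0(y)/q(y)``; a
    sampled ancestor contributes ``psi``; an extant sampled tip (age 0)
    contributes ``rho``.  Sampled ancestors are recognised as tips on
    zero-duration pendant branches, whose attachment nodes are not
    counted as bifurcations.
    """
    params.validate()
    c1, c2 = _c1_c2(params)
    if tree.root.age > params.origin:
        raise InvalidDensityError(
            f"root age {tree.root.age} exceeds origin {params.origin}")
    logp = _log_q(params.origin, c1, c2)
    for nd in tree.postorder():
        if nd.is_tip:
            if nd.age > params.origin + eps:
                raise InvalidDensityError("tip older than origin")
            if tree.is_sampled_ancestor(nd):
                if params.sampling <= 0:
                    return -math.inf
                logp += math.log(params.sampling)
            elif nd.age <= eps:  # extant sample
                if params.rho <= 0:
                    return -math.inf
                logp += math.log(params.rho)
            else:  # fossil leaf
                if params.sampling <= 0:
                    return -math.inf
                p0 = _p0(nd.age, params, c1, c2)
                if p0 <= 0:
                    return -math.inf
                logp += math.log(params.sampling) + math.log(p0) \
                    - _log_q(nd.age, c1, c2)
        else:
            is_sa_attachment = any(
                ch.is_tip and (nd.age - ch.age) <= eps for ch in nd.children)
            if not is_sa_attachment:
                logp += math.log(params.birth) + _log_q(nd.age, c1, c2)
    return logp


# ---------------------------------------------------------------------------
# Fossil-site tip-age priors
# ---------------------------------------------------------------------------

@dataclass
class FossilSite:
    name: str
    min_age: float
    max_age: float
    taxa: List[str]

    def __post_init__(self) -> None:
        if self.min_age > self.max_age:
            raise ValueError(f"site {self.name}: min_age > max_age")


@dataclass
class SiteAgeParams:
    """Current age of each fossil site, with uniform bounds."""

    sites: List[FossilSite]
    ages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site in self.sites:
            self.ages.setdefault(site.name, 0.5 * (site.min_age + site.max_age))

    def site_of(self, taxon: str) -> Optional[FossilSite]:
        for site in self.sites:
            if taxon in site.taxa:
                return site
        return None

    def tip_age(self, taxon: str) -> Optional[float]:
        site = self.site_of(taxon)
        return None if site is None else self.ages[site.name]

    def log_density(self) -> float:
        total = 0.0
        for site in self.sites:
            a = self.ages[site.name]
            if not site.min_age <= a <= site.max_age:
                return -math.inf
            if site.max_age > site.min_age:
                total -= math.log(site.max_age - site.min_age)
        return total


# ---------------------------------------------------------------------------
# Relaxed clock
# ---------------------------------------------------------------------------

@dataclass
class RelaxedClock:
    """Uncorrelated lognormal relaxed clock.

    Branch-rate multipliers are i.i.d. LogNormal with real-space mean 1
    and log-space standard deviation ``sigma``; the branch substitution
    rate is ``clock_rate`` times the multiplier.
    """

    clock_rate: float
    sigma: float

    def multiplier_log_density(self, multipliers: Iterable[float]) -> float:
        mu = -0.5 * self.sigma ** 2
        total = 0.0
        for m in multipliers:
            if m <= 0:
                return -math.inf
            total += lognormal_logpdf(m, mu, self.sigma)
        return float(total)


# ---------------------------------------------------------------------------
# Monophyly constraints
# ---------------------------------------------------------------------------

def check_monophyly(tree: TimeTree, constraints: Sequence[Iterable[str]]) -> bool:
    """True iff every constraint set forms a clade of ``tree``."""
    tips = set(tree.tip_labels())
    for constraint in constraints:
        cset = frozenset(constraint)
        unknown = cset - tips
        if unknown:
            raise KeyError(f"constraint taxa not in tree: {sorted(unknown)}")
        if len(cset) <= 1:
            continue
        if not tree.is_clade(cset):
            return False
    return True


# ---------------------------------------------------------------------------
# Parameter priors
# ---------------------------------------------------------------------------

def lognormal(real_space_mean: Optional[float] = None, sigma: float = 1.0,
              log_mean: Optional[float] = None):
    """Lognormal distribution, parameterised either by its real-space
    mean (with ``sigma`` in log space) or directly by log-space mean."""
    if (real_space_mean is None) == (log_mean is None):
        raise ValueError("give exactly one of real_space_mean / log_mean")
    if real_space_mean is not None:
        mu = math.log(real_space_mean) - 0.5 * sigma ** 2
    else:
        mu = log_mean
    return stats.lognorm(s=sigma, scale=math.exp(mu))


@dataclass
class PriorConfig:
    """Hyper-priors of the analysis; defaults follow the study design.

    birth: lognormal with real-space mean 0.14 and log-space sd 0.9
    death, sampling: exponential with mean 0.1
    clock rate: lognormal with log-space mean -5.5, sd 2
    clock sd: exponential with mean 1
    partition rates: normal(1, 2), truncated to positive by rejection
    homology states: uniform
    origin: uniform on [0, origin_max]
    """

    birth_real_space_mean: float = 0.14
    birth_sigma: float = 0.9
    birth_sigma_real_space: bool = False
    death_mean: float = 0.1
    sampling_mean: float = 0.1
    clock_log_mean: float = -5.5
    clock_sigma: float = 2.0
    clock_sd_mean: float = 1.0
    rate_prior_mean: float = 1.0
    rate_prior_sd: float = 2.0
    origin_max: float = 1000.0

    def birth_dist(self):
        sigma = self.birth_sigma
        if self.birth_sigma_real_space:
            # convert a real-space sd to the log-space sigma of a
            # lognormal with the given real-space mean
            m = self.birth_real_space_mean
            sigma = math.sqrt(math.log(1.0 + (self.birth_sigma / m) ** 2))
        return lognormal(real_space_mean=self.birth_real_space_mean, sigma=sigma)

    def death_dist(self):
        return stats.expon(scale=self.death_mean)

    def sampling_dist(self):
        return stats.expon(scale=self.sampling_mean)

    def clock_rate_dist(self):
        return lognormal(log_mean=self.clock_log_mean, sigma=self.clock_sigma)

    def clock_sd_dist(self):
        return stats.expon(scale=self.clock_sd_mean)

    def rate_dist(self):
        return stats.norm(loc=self.rate_prior_mean, scale=self.rate_prior_sd)

    # log-space parameters used by the fast log-pdf path
    def birth_log_mu_sigma(self) -> Tuple[float, float]:
        sigma = self.birth_sigma
        if self.birth_sigma_real_space:
            m = self.birth_real_space_mean
            sigma = math.sqrt(math.log(1.0 + (self.birth_sigma / m) ** 2))
        mu = math.log(self.birth_real_space_mean) - 0.5 * sigma ** 2
        return mu, sigma


def prior_log_density(state, priors: PriorConfig,
                      constraints: Sequence[FrozenSet[str]] = (),
                      include_tree_prior: bool = True) -> float:
    """Joint log prior of a full model state; -inf outside support.

    ``state`` is a :class:`dynhom.mcmc.ModelState`.  The total is the sum
    of the FBD tree density, site-age uniforms, clock priors, the
    birth/death/sampling hyper-priors, partition-rate normals and the
    uniform homology prior; monophyly violations return -inf.
    """
    total = 0.0
    # hard constraints first
    try:
        if constraints and not check_monophyly(state.tree, constraints):
            return -math.inf
    except KeyError:
        raise
    fbd = state.fbd
    if fbd.origin < state.tree.root.age or fbd.origin > priors.origin_max:
        return -math.inf
    if fbd.birth <= 0 or fbd.death <= 0 or fbd.sampling <= 0:
        return -math.inf
    for site in state.site_ages.sites:
        a = state.site_ages.ages[site.name]
        if not site.min_age <= a <= site.max_age:
            return -math.inf
    sa = state.site_ages.log_density()
    if not math.isfinite(sa):
        return -math.inf
    total += sa
    if include_tree_prior:
        try:
            t = fbd_log_density(state.tree, fbd)
        except InvalidDensityError:
            return -math.inf
        if not math.isfinite(t):
            return -math.inf
        total += t
        total -= math.log(priors.origin_max)  # uniform origin prior
    b_mu, b_sigma = priors.birth_log_mu_sigma()
    total += lognormal_logpdf(fbd.birth, b_mu, b_sigma)
    total += exponential_logpdf(fbd.death, priors.death_mean)
    total += exponential_logpdf(fbd.sampling, priors.sampling_mean)
    clock = state.clock
    if clock.clock_rate <= 0 or clock.sigma <= 0:
        return -math.inf
    total += lognormal_logpdf(clock.clock_rate, priors.clock_log_mean,
                              priors.clock_sigma)
    total += exponential_logpdf(clock.sigma, priors.clock_sd_mean)
    mults = [nd.rate_multiplier for nd in state.tree.postorder()
             if nd.parent is not None]
    total += clock.multiplier_log_density(mults)
    rates = state.partition_model.rates
    if np.any(rates <= 0):
        return -math.inf
    for r in rates:
        total += normal_logpdf(float(r), priors.rate_prior_mean,
                               priors.rate_prior_sd)
    for h, block in zip(state.homology, state.blocks):
        if not 0 <= h < block.state_count:
            return -math.inf
        total -= math.log(block.state_count)
    return float(total)
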