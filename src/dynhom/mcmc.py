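"""Metropolis-Hastings sampler over trees, clocks, rates and homology states.

The state is a dated sampled-ancestor tree plus relaxed-clock, partition
rate, birth-death and fossil-site-age parameters and one integer
homology state per block.  The operator set covers scale moves on all
scalar parameters, node-age and root moves, a sampled-ancestor-aware
Wilson-Balding branch move and exchange move (each also available as a
joint variant that simultaneously redraws the homology state), a
reversible-jump leaf/sampled-ancestor toggle, a weight-preserving
delta exchange on partition rates, fossil-site age redraws and the
homology flip.

Moves that violate monophyly constraints or age ordering are proposed
and rejected through a -inf prior, keeping proposal machinery simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .homology import HomologyLikelihoodBank, HomologyTrace
from .matrix import HomologyBlock, MorphMatrix, PartitionScheme
from .mk import MkLikelihood, MkPartitionModel
from .priors import (FBDParams, PriorConfig, RelaxedClock, SiteAgeParams,
                     prior_log_density)
from .tree import SA_EPS, Node, TimeTree

__all__ = [
    "ModelState", "McmcConfig", "McmcResult", "run_mcmc", "ess",
    "majority_rule_consensus", "n_samples", "burnin_discard",
    "retained_sample_count", "OperatorSchedule",
]


# ---------------------------------------------------------------------------
# Sample-count arithmetic
# ---------------------------------------------------------------------------

def n_samples(chain_length: int, sample_every: int) -> int:
    """Number of logged samples, counting the initial state as sample 0."""
    if chain_length % sample_every:
        raise ValueError("chain length must be divisible by the sample interval")
    return chain_length // sample_every + 1

def burnin_discard(n: int, fraction: float) -> int:
    """Samples discarded as burn-in: floor(fraction * n)."""
    if not 0 <= fraction < 1:
        raise ValueError("burn-in fraction must lie in [0, 1)")
    return math.floor(fraction * n)

def retained_sample_count(chain_length: int, sample_every: int,
                          burnin_fraction: float) -> int:
    n = n_samples(chain_length, sample_every)
    return n - burnin_discard(n, burnin_fraction)


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

class ModelState:
    """Full MCMC state with cached posterior components.

    The likelihood factorises into a fixed-homology partition engine and
    one likelihood bank per homology block; dirty flags keep the caches
    equal to a fresh pruning computation whenever they are read.
    """

    def __init__(self, tree: TimeTree, fixed: MorphMatrix,
                 blocks: Sequence[HomologyBlock],
                 scheme: PartitionScheme,
                 partition_model: MkPartitionModel,
                 clock: RelaxedClock, fbd: FBDParams,
                 site_ages: SiteAgeParams,
                 homology: Optional[Sequence[int]] = None,
                 priors: Optional[PriorConfig] = None,
                 constraints: Sequence[FrozenSet[str]] = (),
                 mkv: bool = False,
                 sample_from_prior: bool = False,
                 include_tree_prior: bool = True):
        self.tree = tree
        self.fixed = fixed
        self.blocks = list(blocks)
        self.scheme = scheme
        self.partition_model = partition_model
        self.clock = clock
        self.fbd = fbd
        self.site_ages = site_ages
        self.homology = list(homology) if homology is not None else [0] * len(self.blocks)
        self.priors = priors or PriorConfig()
        self.constraints = [frozenset(c) for c in constraints]
        self.sample_from_prior = sample_from_prior
        self.include_tree_prior = include_tree_prior

        # composite column order: fixed columns, then each block's columns
        n_fixed = fixed.n_char
        widths = [b.n_char for b in self.blocks]
        if len(scheme.assignment) != n_fixed + sum(widths):
            raise ValueError("partition scheme does not cover the composite matrix")
        self._slices = []
        start = n_fixed
        for w in widths:
            self._slices.append(slice(start, start + w))
            start += w

        self.fixed_engine = MkLikelihood(fixed, mkv=mkv) if n_fixed else None
        self.banks = [HomologyLikelihoodBank(b, mkv=mkv) for b in self.blocks]
        self._ll_fixed = np.nan
        self._fixed_dirty = True

    # -- rates ----------------------------------------------------------
    def char_rates(self) -> np.ndarray:
        return np.array([self.partition_model.rates[p]
                         for p in self.scheme.assignment])

    def fixed_char_rates(self) -> np.ndarray:
        return self.char_rates()[: self.fixed.n_char]

    def block_char_rates(self, b: int) -> np.ndarray:
        return self.char_rates()[self._slices[b]]

    # -- cache control ---------------------------------------------------
    def mark_likelihood_dirty(self) -> None:
        self._fixed_dirty = True
        for bank in self.banks:
            bank.mark_all_dirty()

    def snapshot_caches(self):
        return (self._ll_fixed, self._fixed_dirty,
                [(b._cache.copy(), b._dirty.copy()) for b in self.banks])

    def restore_caches(self, snap) -> None:
        self._ll_fixed, self._fixed_dirty = snap[0], snap[1]
        for bank, (c, d) in zip(self.banks, snap[2]):
            bank._cache = c
            bank._dirty = d

    # -- posterior components ---------------------------------------------
    def log_likelihood(self) -> float:
        if self.sample_from_prior:
            return 0.0
        total = 0.0
        if self.fixed_engine is not None:
            if self._fixed_dirty:
                self._ll_fixed = self.fixed_engine.loglik(
                    self.tree, self.clock.clock_rate, self.fixed_char_rates())
                self._fixed_dirty = False
            total += self._ll_fixed
        for b, bank in enumerate(self.banks):
            total += bank.loglik(self.homology[b], self.tree,
                                 self.clock.clock_rate, self.block_char_rates(b))
        return total

    def log_prior(self) -> float:
        return prior_log_density(self, self.priors, self.constraints,
                                 include_tree_prior=self.include_tree_prior)

    def log_posterior(self) -> float:
        lp = self.log_prior()
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.log_likelihood()

    def all_block_logliks(self) -> List[np.ndarray]:
        """Per-state tree likelihoods of every block (refreshing caches)."""
        if self.sample_from_prior:
            return [np.zeros(b.state_count) for b in self.blocks]
        return [bank.all_logliks(self.tree, self.clock.clock_rate,
                                 self.block_char_rates(b))
                for b, bank in enumerate(self.banks)]

    def audit(self) -> None:
        """Verify cached likelihoods against a fresh recomputation."""
        snap = self.snapshot_caches()
        cached = self.log_likelihood()
        self.mark_likelihood_dirty()
        fresh = self.log_likelihood()
        if not math.isclose(cached, fresh, rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(f"stale likelihood cache: {cached} vs {fresh}")
        self.restore_caches(snap)
        self.tree.validate()


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

class Operator:
    name = "operator"
    tunable = False

    def __init__(self, weight: float = 1.0, tuning: float = 1.0):
        self.weight = weight
        self.tuning = tuning
        self.proposed = 0
        self.accepted = 0
        self._undo: Optional[Callable[[], None]] = None

    def propose(self, state: ModelState, rng: np.random.Generator) -> Optional[float]:
        raise NotImplementedError

    def undo(self) -> None:
        if self._undo is not None:
            self._undo()
            self._undo = None

    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0

    def tune(self, target: float = 0.234) -> None:
        if not self.tunable or self.proposed < 20:
            return
        rate = self.acceptance_rate()
        self.tuning = float(np.clip(self.tuning * math.exp(rate - target),
                                    1e-4, 1e4))


class ScaleOperator(Operator):
    """Multiplicative scale move on one positive scalar; log HR = log s."""

    tunable = True

    def __init__(self, name: str, getter, setter, weight: float = 1.0,
                 tuning: float = 0.5, dirty_likelihood: bool = False):
        super().__init__(weight, tuning)
        self.name = name
        self.getter = getter
        self.setter = setter
        self.dirty_likelihood = dirty_likelihood

    def propose(self, state, rng):
        old = self.getter(state)
        s = math.exp(self.tuning * (rng.random() - 0.5))
        self.setter(state, old * s)
        if self.dirty_likelihood:
            snap = state.snapshot_caches()
            state.mark_likelihood_dirty()

            def undo():
                self.setter(state, old)
                state.restore_caches(snap)
        else:
            def undo():
                self.setter(state, old)
        self._undo = undo
        return math.log(s)


class NodeAgeOperator(Operator):
    """Uniform redraw of one internal node's age within its bracket."""

    name = "node_age_uniform"

    def propose(self, state, rng):
        tree = state.tree
        eligible = [nd for nd in tree.internals()
                    if nd.parent is not None and not _is_sa_attachment(tree, nd)]
        if not eligible:
            return None
        nd = eligible[rng.integers(len(eligible))]
        lower = max(ch.age for ch in nd.children)
        upper = nd.parent.age
        if upper <= lower:
            return None
        old = nd.age
        nd.age = lower + rng.random() * (upper - lower)
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            nd.age = old
            state.restore_caches(snap)

        self._undo = undo
        return 0.0


class RootScaleOperator(Operator):
    """Scale the root's stem excess above its oldest child."""

    name = "root_scale"
    tunable = True

    def __init__(self, weight: float = 1.0, tuning: float = 0.5):
        super().__init__(weight, tuning)

    def propose(self, state, rng):
        root = state.tree.root
        base = max(ch.age for ch in root.children)
        excess = root.age - base
        if excess <= 0:
            return None
        s = math.exp(self.tuning * (rng.random() - 0.5))
        old = root.age
        root.age = base + excess * s
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            root.age = old
            state.restore_caches(snap)

        self._undo = undo
        return math.log(s)


class OriginOperator(Operator):
    """Uniform redraw of the origin on (root age, origin_max); HR = 0."""

    name = "origin_uniform"

    def propose(self, state, rng):
        lo = state.tree.root.age
        hi = state.priors.origin_max
        if hi <= lo:
            return None
        old = state.fbd.origin
        state.fbd.origin = lo + rng.random() * (hi - lo)
        self._undo = lambda: setattr(state.fbd, "origin", old)
        return 0.0


class SiteAgeOperator(Operator):
    """Uniform redraw of one fossil site's age within its bounds.

    All member tips move with the site; sampled-ancestor attachments
    move with their tips.  Age-order violations are rejected here (the
    likelihood would be undefined on negative durations).
    """

    name = "site_age_uniform"

    def propose(self, state, rng):
        sites = state.site_ages.sites
        if not sites:
            return None
        site = sites[rng.integers(len(sites))]
        old_age = state.site_ages.ages[site.name]
        new_age = site.min_age + rng.random() * (site.max_age - site.min_age)
        tree = state.tree
        moved: List[Tuple[Node, float]] = []
        ok = True
        for label in site.taxa:
            try:
                tip = tree.find_tip(label)
            except KeyError:
                continue
            was_sa = tree.is_sampled_ancestor(tip)
            moved.append((tip, tip.age))
            tip.age = new_age
            if was_sa:
                par = tip.parent
                moved.append((par, par.age))
                par.age = new_age
        for nd, _ in moved:
            if nd.parent is not None and nd.parent.age < nd.age - SA_EPS:
                ok = False
            for ch in nd.children:
                if ch.age > nd.age + SA_EPS:
                    ok = False
        state.site_ages.ages[site.name] = new_age
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            for nd, age in moved:
                nd.age = age
            state.site_ages.ages[site.name] = old_age
            state.restore_caches(snap)

        self._undo = undo
        if not ok:
            return None
        return 0.0


class HomologyFlipOperator(Operator):
    """Uniform redraw of one block's homology state among the others."""

    name = "homology_flip"

    def propose(self, state, rng):
        if not state.blocks:
            return None
        b = int(rng.integers(len(state.blocks)))
        n = state.blocks[b].state_count
        old = state.homology[b]
        choices = [h for h in range(n) if h != old]
        state.homology[b] = int(choices[rng.integers(len(choices))])
        self._undo = lambda: state.homology.__setitem__(b, old)
        return 0.0


def _is_sa_attachment(tree: TimeTree, nd: Node) -> bool:
    return any(ch.is_tip and (nd.age - ch.age) <= SA_EPS for ch in nd.children)


def _propose_wilson_balding(state: ModelState, rng: np.random.Generator):
    """SA-aware Wilson-Balding; returns (log HR, undo) or None.

    Draw a prune node i and a target j uniformly from all non-root
    nodes and auto-reject invalid pairs, which keeps the draw
    probabilities symmetric; the Hastings ratio is then the ratio of
    the reattachment-interval lengths.  Nodes adjacent to
    sampled-ancestor attachments are skipped so the move stays within a
    fixed-dimension subspace (the leaf/SA jump handles conversions).
    """
    tree = state.tree
    nodes = [nd for nd in tree.postorder() if nd.parent is not None]
    i = nodes[rng.integers(len(nodes))]
    j = nodes[rng.integers(len(nodes))]
    p = i.parent
    if p is None or p.parent is None:       # i's parent must not be root
        return None
    if _is_sa_attachment(tree, p):          # sibling (or i) is an SA tip
        return None
    sib = p.children[0] if p.children[1] is i else p.children[1]
    if j is i or j is p or j is sib:
        return None
    # j must not be inside the subtree of i
    anc = j
    while anc is not None:
        if anc is i:
            return None
        anc = anc.parent
    pj = j.parent
    new_lower = max(i.age, j.age)
    new_upper = pj.age
    if new_upper <= new_lower:
        return None
    g = p.parent
    old_lower = max(i.age, sib.age)
    old_upper = g.age
    old_p_age = p.age

    # detach: replace p by sib under g
    gi = g.children.index(p)
    g.children[gi] = sib
    sib.parent = g
    # reattach p (with child i) on edge above j; pj is unchanged by the
    # detach (j is not i, sib or p)
    ji = pj.children.index(j)
    pj.children[ji] = p
    p.parent = pj
    p.children = [i, j]
    i.parent = p
    j.parent = p
    p.age = new_lower + rng.random() * (new_upper - new_lower)

    def undo():
        # detach p from above j
        pj.children[ji] = j
        j.parent = pj
        # restore p above sib under g
        g.children[gi] = p
        p.parent = g
        p.children = [i, sib]
        i.parent = p
        sib.parent = p
        p.age = old_p_age

    log_hr = math.log((new_upper - new_lower) / (old_upper - old_lower))
    return log_hr, undo


def _propose_exchange(state: ModelState, rng: np.random.Generator):
    """SA-aware wide exchange: swap two non-nested subtrees; HR = 0."""
    tree = state.tree
    nodes = [nd for nd in tree.postorder() if nd.parent is not None]
    a = nodes[rng.integers(len(nodes))]
    b = nodes[rng.integers(len(nodes))]
    if a is b or a.parent is b.parent:
        return None
    pa, pb = a.parent, b.parent
    if _is_sa_attachment(tree, pa) or _is_sa_attachment(tree, pb):
        return None
    # no ancestor relation
    anc = pa
    while anc is not None:
        if anc is b:
            return None
        anc = anc.parent
    anc = pb
    while anc is not None:
        if anc is a:
            return None
        anc = anc.parent
    if pa.age <= b.age or pb.age <= a.age:
        return None
    ia = pa.children.index(a)
    ib = pb.children.index(b)
    pa.children[ia] = b
    pb.children[ib] = a
    a.parent, b.parent = pb, pa

    def undo():
        pa.children[ia] = a
        pb.children[ib] = b
        a.parent, b.parent = pa, pb

    return 0.0, undo


class TreeOperator(Operator):
    """Wrap a tree-move proposal function, with optional joint homology
    redraw (the joint variants explore correlated tree/homology space)."""

    def __init__(self, name: str, move, weight: float = 1.0,
                 with_homology: bool = False):
        super().__init__(weight)
        self.name = name
        self.move = move
        self.with_homology = with_homology

    def propose(self, state, rng):
        result = self.move(state, rng)
        if result is None:
            return None
        log_hr, undo_tree = result
        old_h = list(state.homology)
        if self.with_homology and state.blocks:
            for b, block in enumerate(state.blocks):
                n = block.state_count
                choices = [h for h in range(n) if h != state.homology[b]]
                state.homology[b] = int(choices[rng.integers(len(choices))])
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            undo_tree()
            state.homology[:] = old_h
            state.restore_caches(snap)

        self._undo = undo
        return log_hr


class LeafToSampledAncestorJump(Operator):
    """Reversible-jump toggle between a pendant fossil leaf and a
    sampled ancestor (zero-length attachment)."""

    name = "leaf_sa_jump"

    def propose(self, state, rng):
        tree = state.tree
        tips = [t for t in tree.tips()
                if t.age > SA_EPS and t.parent is not None]
        if not tips:
            return None
        tip = tips[rng.integers(len(tips))]
        p = tip.parent
        sib = p.children[0] if p.children[1] is tip else p.children[1]
        upper = p.parent.age if p.parent is not None else state.fbd.origin
        lower = max(tip.age, sib.age)
        old_age = p.age
        if tree.is_sampled_ancestor(tip):
            # expand: draw a positive attachment height
            if upper <= lower:
                return None
            p.age = lower + rng.random() * (upper - lower)
            log_hr = math.log(upper - lower)
        else:
            # collapse to sampled ancestor
            if sib.age > tip.age + SA_EPS:
                return None
            if upper <= lower:
                return None
            p.age = tip.age
            log_hr = -math.log(upper - lower)
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            p.age = old_age
            state.restore_caches(snap)

        self._undo = undo
        return log_hr


class RateDeltaExchange(Operator):
    """Transfer rate mass between two partitions, conserving the
    weighted mean at one."""

    name = "rate_delta_exchange"
    tunable = True

    def __init__(self, weight: float = 1.0, tuning: float = 0.2):
        super().__init__(weight, tuning)

    def propose(self, state, rng):
        model = state.partition_model
        n = len(model.rates)
        if n < 2:
            return None
        i, j = rng.choice(n, size=2, replace=False)
        delta = rng.random() * self.tuning
        old_i, old_j = model.rates[i], model.rates[j]
        new_i = old_i - delta / model.weights[i]
        new_j = old_j + delta / model.weights[j]
        if new_i <= 0 or new_j <= 0:
            return None
        model.rates[i] = new_i
        model.rates[j] = new_j
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            model.rates[i] = old_i
            model.rates[j] = old_j
            state.restore_caches(snap)

        self._undo = undo
        return 0.0


class BranchRateOperator(Operator):
    """Scale one branch's relaxed-clock rate multiplier."""

    name = "branch_rate_scale"
    tunable = True

    def __init__(self, weight: float = 1.0, tuning: float = 0.8):
        super().__init__(weight, tuning)

    def propose(self, state, rng):
        nodes = [nd for nd in state.tree.postorder() if nd.parent is not None]
        nd = nodes[rng.integers(len(nodes))]
        s = math.exp(self.tuning * (rng.random() - 0.5))
        old = nd.rate_multiplier
        nd.rate_multiplier = old * s
        snap = state.snapshot_caches()
        state.mark_likelihood_dirty()

        def undo():
            nd.rate_multiplier = old
            state.restore_caches(snap)

        self._undo = undo
        return math.log(s)


@dataclass
class OperatorSchedule:
    """Weighted operator list with a seeded RNG."""

    operators: List[Operator]
    rng: np.random.Generator

    def __post_init__(self) -> None:
        if any(op.weight <= 0 for op in self.operators):
            raise ValueError("operator weights must be positive")
        w = np.array([op.weight for op in self.operators], dtype=float)
        self._probs = w / w.sum()

    def draw(self) -> Operator:
        return self.operators[self.rng.choice(len(self.operators), p=self._probs)]


def default_operators(state: ModelState) -> List[Operator]:
    """The minimal irreducible operator set for SA tree + homology space."""
    ops: List[Operator] = [
        ScaleOperator("birth_scale",
                      lambda s: s.fbd.birth,
                      lambda s, v: setattr(s.fbd, "birth", v), weight=1.0),
        ScaleOperator("death_scale",
                      lambda s: s.fbd.death,
                      lambda s, v: setattr(s.fbd, "death", v), weight=1.0),
        ScaleOperator("sampling_scale",
                      lambda s: s.fbd.sampling,
                      lambda s, v: setattr(s.fbd, "sampling", v), weight=1.0),
        ScaleOperator("clock_rate_scale",
                      lambda s: s.clock.clock_rate,
                      lambda s, v: setattr(s.clock, "clock_rate", v),
                      weight=2.0, dirty_likelihood=True),
        ScaleOperator("clock_sigma_scale",
                      lambda s: s.clock.sigma,
                      lambda s, v: setattr(s.clock, "sigma", v), weight=1.0),
        OriginOperator(weight=1.0),
        NodeAgeOperator(weight=6.0),
        RootScaleOperator(weight=1.0),
        TreeOperator("sa_wilson_balding", _propose_wilson_balding, weight=6.0),
        TreeOperator("sa_exchange", _propose_exchange, weight=6.0),
        LeafToSampledAncestorJump(weight=2.0),
        BranchRateOperator(weight=4.0),
    ]
    if state.site_ages.sites:
        ops.append(SiteAgeOperator(weight=2.0))
    if len(state.partition_model.rates) >= 2:
        ops.append(RateDeltaExchange(weight=2.0))
    if state.blocks:
        ops.append(HomologyFlipOperator(weight=2.0))
        ops.append(TreeOperator("homology_sa_wilson_balding",
                                _propose_wilson_balding, weight=2.0,
                                with_homology=True))
        ops.append(TreeOperator("homology_sa_exchange", _propose_exchange,
                                weight=2.0, with_homology=True))
    return ops


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    chain_length: int = 100_000
    sample_every: int = 100
    burnin_fraction: float = 0.1
    seed: int = 1
    tune: bool = True
    audit_every: int = 0          # verify caches every n generations (0 = off)

    def __post_init__(self) -> None:
        if self.chain_length % self.sample_every:
            raise ValueError("chain length must be divisible by sample interval")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burn-in fraction must lie in [0, 1)")


@dataclass
class McmcResult:
    trace: pd.DataFrame
    trees: List[str]                      # newick per sample
    tree_objects: List[TimeTree]
    homology_trace: HomologyTrace
    operators: List[Operator]
    config: McmcConfig

    def retained(self) -> pd.DataFrame:
        discard = burnin_discard(len(self.trace), self.config.burnin_fraction)
        return self.trace.iloc[discard:]

    def retained_trees(self) -> List[TimeTree]:
        discard = burnin_discard(len(self.tree_objects), self.config.burnin_fraction)
        return self.tree_objects[discard:]


def run_mcmc(state: ModelState, config: McmcConfig,
             operators: Optional[List[Operator]] = None,
             sample_callback: Optional[Callable[[int, ModelState], None]] = None,
             keep_tree_objects: bool = True) -> McmcResult:
    """Run one Metropolis-Hastings chain; deterministic for a given seed.

    The initial state is logged as sample 0; thereafter every
    ``sample_every`` generations.  ``sample_callback`` runs at each
    logged sample (used for ancestral sequence logging).
    """
    rng = np.random.default_rng(config.seed)
    ops = operators if operators is not None else default_operators(state)
    schedule = OperatorSchedule(ops, rng)

    log_post = state.log_posterior()
    if not math.isfinite(log_post):
        raise ValueError(
            "non-finite posterior at initialisation; start the chain from a "
            "prior-compatible state (check constraints, site ages and origin)")

    rows: List[Dict[str, float]] = []
    trees: List[str] = []
    tree_objects: List[TimeTree] = []
    htrace = HomologyTrace()
    tune_until = int(config.burnin_fraction * config.chain_length)

    def log_sample(gen: int) -> None:
        lp = state.log_prior()
        ll = state.log_likelihood()
        row: Dict[str, float] = {
            "generation": gen,
            "posterior": lp + ll,
            "likelihood": ll,
            "prior": lp,
            "clock_rate": state.clock.clock_rate,
            "clock_sigma": state.clock.sigma,
            "birth": state.fbd.birth,
            "death": state.fbd.death,
            "sampling": state.fbd.sampling,
            "origin": state.fbd.origin,
            "root_age": state.tree.root.age,
        }
        for p, r in enumerate(state.partition_model.rates):
            row[f"rate_{p}"] = float(r)
        for site in state.site_ages.sites:
            row[f"age_{site.name}"] = state.site_ages.ages[site.name]
        block_lls = state.all_block_logliks()
        for b, lls in enumerate(block_lls):
            row[f"h_{b}"] = state.homology[b]
            for h, v in enumerate(lls):
                row[f"ll_block{b}_h{h}"] = float(v)
        if state.blocks:
            htrace.append(gen, state.homology[0], block_lls[0])
        rows.append(row)
        trees.append(state.tree.newick())
        if keep_tree_objects:
            tree_objects.append(state.tree.copy())
        if sample_callback is not None:
            sample_callback(gen, state)

    log_sample(0)
    for gen in range(1, config.chain_length + 1):
        op = schedule.draw()
        op.proposed += 1
        op._undo = None  # guard against stale undo from an accepted move
        log_hr = op.propose(state, rng)
        if log_hr is None:
            op.undo()
        else:
            new_post = state.log_posterior()
            delta = new_post - log_post + log_hr
            if delta >= 0 or math.log(rng.random()) < delta:
                op.accepted += 1
                log_post = new_post
            else:
                op.undo()
        if config.tune and gen <= tune_until and gen % 100 == 0:
            for o in ops:
                o.tune()
                o.proposed = 0
                o.accepted = 0
        if config.audit_every and gen % config.audit_every == 0:
            state.audit()
            fresh = state.log_posterior()
            if not math.isclose(fresh, log_post, rel_tol=1e-9, abs_tol=1e-6):
                raise AssertionError(
                    f"posterior cache drift at gen {gen}: {log_post} vs {fresh}")
            log_post = fresh
        if gen % config.sample_every == 0:
            log_sample(gen)

    return McmcResult(trace=pd.DataFrame(rows), trees=trees,
                      tree_objects=tree_objects, homology_trace=htrace,
                      operators=ops, config=config)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def ess(samples: Sequence[float]) -> float:
    """Effective sample size via the autocorrelation-time estimate.

    Anti-correlated chains can yield nominal ESS above the sample count;
    the value is clamped to n.  A constant trace has undefined ESS and
    returns NaN.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.allclose(x, x[0]):
        return float("nan")
    import arviz

    value = float(arviz.ess(x))
    return min(value, float(len(x)))


# ---------------------------------------------------------------------------
# Majority-rule consensus with time annotation
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNode:
    clade: FrozenSet[str]
    frequency: float
    mean_age: float
    children: List["ConsensusNode"] = field(default_factory=list)


def majority_rule_consensus(trees: Sequence[TimeTree],
                            threshold: float = 0.5) -> ConsensusNode:
    """Majority-rule consensus with posterior frequencies and mean ages.

    Clades with frequency strictly above ``threshold`` are retained;
    each consensus node is annotated with its clade's frequency and the
    mean MRCA age over the trees that contain the clade.  Tip ages are
    averaged the same way (sites may move tip ages between samples).
    """
    if not trees:
        raise ValueError("need at least one tree")
    tip_set = frozenset(trees[0].tip_labels())
    counts: Dict[FrozenSet[str], int] = {}
    age_sums: Dict[FrozenSet[str], float] = {}
    for tree in trees:
        if frozenset(tree.tip_labels()) != tip_set:
            raise ValueError("trees have differing tip sets")
        sets = tree.clade_sets()
        seen = set()
        for nd in tree.postorder():
            clade = sets[id(nd)]
            if clade in seen:     # zero-length SA attachments duplicate sets
                continue
            seen.add(clade)
            counts[clade] = counts.get(clade, 0) + 1
            age_sums[clade] = age_sums.get(clade, 0.0) + nd.age
    n = len(trees)
    kept = [c for c, k in counts.items()
            if k / n > threshold or len(c) == 1 or c == tip_set]
    kept.sort(key=lambda c: (-len(c), sorted(c)))
    nodes = [ConsensusNode(clade=c, frequency=counts[c] / n,
                           mean_age=age_sums[c] / counts[c]) for c in kept]
    roots: List[ConsensusNode] = []
    for i, nd in enumerate(nodes):
        parent = None
        for j in range(i - 1, -1, -1):
            if nd.clade < nodes[j].clade:
                if parent is None or len(nodes[j].clade) < len(parent.clade):
                    parent = nodes[j]
        if parent is None:
            roots.append(nd)
        else:
            parent.children.append(nd)
    assert len(roots) == 1
    return roots[0]


def consensus_newick(node: ConsensusNode, fmt: str = "%.6g") -> str:
    def rec(nd: ConsensusNode) -> str:
        if not nd.children:
            return sorted(nd.clade)[0]
        inner = ",".join(rec(c) for c in nd.children)
        return f"({inner}){fmt % nd.frequency}"

    return rec(node) + ";"
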