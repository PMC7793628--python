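"""Dynamic homology: per-state tree likelihoods and the multiplexer.

Each homology state ``h`` of a block indexes an alternative composite
alignment (fixed characters + coding ``h``).  A
:class:`HomologyLikelihoodBank` holds one pruning engine per state with
cached log-likelihoods and dirty flags; the multiplexer passes the
active state's value to the posterior.  The MCMC spends more time in the
state whose alignment yields the higher tree likelihood; on a fixed tree
the posterior over states is available analytically as a softmax of the
per-state log-likelihoods (uniform prior over states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .matrix import HomologyBlock, MorphMatrix, compose_matrix
from .mk import MkLikelihood
from .tree import TimeTree


@dataclass
class HomologyParameter:
    """Integer homology state in ``{0..N-1}`` for one block."""

    value: int
    n_states: int
    block_label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.value < self.n_states:
            raise ValueError(
                f"homology state {self.value} out of range 0..{self.n_states - 1}")


class HomologyLikelihoodBank:
    """Cached per-homology-state tree log-likelihoods.

    Parameters
    ----------
    block:
        The homology block (N alternative codings).
    char_rates:
        Per-character rates for the block's columns; shared across
        states, since partition assignment of block characters uses the
        lower-homoplasy key.
    fixed:
        Optional matrix of fixed-homology characters to fold into each
        state's engine.  The MCMC keeps the fixed partition in a
        separate engine (the factorisation is exact), so per-state
        values are the homology partition's own tree likelihoods; the
        fixed part cancels in the softmax over states either way.
    """

    def __init__(self, block: HomologyBlock,
                 char_rates: Optional[Sequence[float]] = None,
                 mkv: bool = False, fixed: Optional[MorphMatrix] = None):
        self.block = block
        self.engines: List[MkLikelihood] = []
        for h in range(block.state_count):
            data = compose_matrix(fixed, block, h) if fixed is not None \
                else block.codings[h]
            full_rates = None
            if char_rates is not None:
                rates = list(char_rates)
                if fixed is not None:
                    rates = [1.0] * fixed.n_char + rates
                full_rates = rates
            self.engines.append(MkLikelihood(data, full_rates, mkv=mkv))
        self.n_states = block.state_count
        self._cache = np.full(self.n_states, np.nan)
        self._dirty = np.ones(self.n_states, dtype=bool)

    def mark_all_dirty(self) -> None:
        self._dirty[:] = True

    def is_clean(self, h: int) -> bool:
        return not self._dirty[h]

    def loglik(self, h: int, tree: TimeTree, clock_rate: float = 1.0,
               char_rates: Optional[Sequence[float]] = None) -> float:
        """Log tree likelihood of homology state ``h`` (cache-aware)."""
        if not 0 <= h < self.n_states:
            raise ValueError(f"homology state {h} out of range")
        if self._dirty[h]:
            self._cache[h] = self.engines[h].loglik(tree, clock_rate, char_rates)
            self._dirty[h] = False
        return float(self._cache[h])

    def all_logliks(self, tree: TimeTree, clock_rate: float = 1.0,
                    char_rates: Optional[Sequence[float]] = None) -> np.ndarray:
        """Refresh and return every state's log-likelihood (for logging)."""
        return np.array([self.loglik(h, tree, clock_rate, char_rates)
                         for h in range(self.n_states)])


def multiplexed_loglik(bank: HomologyLikelihoodBank, h: int,
                       tree: TimeTree, clock_rate: float = 1.0,
                       char_rates: Optional[Sequence[float]] = None) -> float:
    """The multiplexer: log-likelihood of the active homology state."""
    return bank.loglik(h, tree, clock_rate, char_rates)


def homology_posterior_from_logliks(logliks: Sequence[float]) -> np.ndarray:
    """Softmax posterior over homology states given per-state
    log-likelihoods and a uniform prior."""
    ll = np.asarray(logliks, dtype=float)
    ll = ll - ll.max()
    w = np.exp(ll)
    return w / w.sum()


def homology_posterior_fixed_tree(tree: TimeTree, block: HomologyBlock,
                                  char_rates: Optional[Sequence[float]] = None,
                                  clock_rate: float = 1.0,
                                  fixed: Optional[MorphMatrix] = None) -> np.ndarray:
    """Analytic posterior over homology states on a fixed tree.

    With tree and parameters held fixed and a uniform prior over states,
    ``P(h) = exp(l_h) / sum_j exp(l_j)``.  (The full-MCMC estimate of
    the homology posterior integrates over trees and so differs from
    this fixed-tree quantity.)
    """
    bank = HomologyLikelihoodBank(block, char_rates, fixed=fixed)
    return homology_posterior_from_logliks(bank.all_logliks(tree, clock_rate))


@dataclass
class HomologyTrace:
    """Per-sample record of the homology machinery.

    Both per-state likelihoods are logged at every sample regardless of
    the active state, so per-state mean log-likelihoods are estimable.
    """

    generations: List[int] = field(default_factory=list)
    states: List[int] = field(default_factory=list)
    state_logliks: List[np.ndarray] = field(default_factory=list)

    def append(self, generation: int, h: int, logliks: Sequence[float]) -> None:
        self.generations.append(int(generation))
        self.states.append(int(h))
        self.state_logliks.append(np.asarray(logliks, dtype=float))

    def posterior_estimate(self, n_states: Optional[int] = None) -> np.ndarray:
        """Frequency of each homology state across logged samples."""
        if not self.states:
            raise ValueError("empty trace")
        n = n_states or (max(self.states) + 1)
        counts = np.bincount(self.states, minlength=n).astype(float)
        return counts / counts.sum()

    def mean_state_logliks(self) -> np.ndarray:
        """Mean log-likelihood per homology state over the trace."""
        return np.vstack(self.state_logliks).mean(axis=0)
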