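"""Mk substitution model and pruning log-likelihood for partitioned matrices.

The Mk model (Lewis-type symmetric k-state CTMC) has the closed-form
transition probabilities::

    P_same(d) = 1/k + (k-1)/k * exp(-k d / (k-1))
    P_diff(d) = 1/k -   1/k   * exp(-k d / (k-1))

for ``d`` expected substitutions.  Because every off-diagonal entry is
equal, ``P @ v`` reduces to ``P_diff * sum(v) + exp(-k d/(k-1)) * v``,
which the pruning pass exploits to avoid building matrices.

Characters are grouped by their model state count; each character
carries its partition's rate multiplier.  Missing and inapplicable cells
contribute all-ones partials; polymorphic cells ones at member states.
Root state frequencies are uniform (the Mk stationary distribution).
Per-node rescaling guards against underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import INAPPLICABLE, MISSING, MorphMatrix, PartitionScheme
from .tree import Node, TimeTree


def mk_transition_prob(k: int, d: float) -> np.ndarray:
    """k-by-k Mk transition probability matrix at ``d`` expected substitutions."""
    if k < 2:
        raise ValueError("Mk model needs k >= 2 states")
    if d < 0:
        raise ValueError("expected substitutions must be non-negative")
    e = np.exp(-k * d / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = 1.0 / k - e / k
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P


@dataclass
class MkPartitionModel:
    """Per-partition Mk rates under the weighted-mean-one constraint."""

    state_counts: List[int]          # model state count per partition
    rates: np.ndarray                # rate multiplier per partition
    weights: np.ndarray              # character count per partition

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("partition rates must be positive")
        self.check_mean_one()

    def weighted_mean(self) -> float:
        return float(np.sum(self.weights * self.rates) / np.sum(self.weights))

    def check_mean_one(self, tol: float = 1e-9) -> None:
        if abs(self.weighted_mean() - 1.0) > tol:
            raise ValueError(
                f"weighted mean of partition rates is {self.weighted_mean()}, not 1")

    @classmethod
    def flat(cls, scheme: PartitionScheme) -> "MkPartitionModel":
        n = scheme.n_partitions
        return cls(
            state_counts=[max(scheme.key[p][0], 2) for p in range(n)],
            rates=np.ones(n),
            weights=np.array([scheme.weights[p] for p in range(n)], dtype=float),
        )


class MkLikelihood:
    """Pruning-algorithm log-likelihood of one composite alignment.

    The alignment and the per-character rates are fixed at construction;
    :meth:`loglik` evaluates any clock tree over the same taxa.
    """

    def __init__(self, matrix: MorphMatrix, char_rates: Optional[Sequence[float]] = None,
                 mkv: bool = False):
        self.matrix = matrix
        self.mkv = mkv
        rates = np.ones(matrix.n_char) if char_rates is None else np.asarray(
            char_rates, dtype=float)
        if len(rates) != matrix.n_char:
            raise ValueError("one rate per character required")
        self.default_rates = rates
        # group characters by model state count (>= 2; constant and
        # all-missing characters are scored under the binary model)
        groups: Dict[int, List[int]] = {}
        for j in range(matrix.n_char):
            k = max(matrix.state_count(j), 2)
            groups.setdefault(k, []).append(j)
        self.groups: List[Tuple[int, np.ndarray, np.ndarray, Dict[str, np.ndarray]]] = []
        for k, cols in sorted(groups.items()):
            cols_arr = np.array(cols)
            grp_rates = rates[cols_arr]
            tip_partials: Dict[str, np.ndarray] = {}
            for taxon, row in zip(matrix.taxa, matrix.cells):
                part = np.zeros((len(cols), k))
                for idx, j in enumerate(cols):
                    cell = row[j]
                    if cell is MISSING or cell is INAPPLICABLE:
                        part[idx, :] = 1.0
                    else:
                        for s_rank, s in enumerate(sorted(matrix.observed_states(j))):
                            if s in cell:
                                part[idx, s_rank] = 1.0
                        if not part[idx].any():
                            # states outside the observed alphabet of a
                            # constant column scored under k=2
                            part[idx, :] = 1.0
                tip_partials[taxon] = part
            self.groups.append((k, cols_arr, grp_rates, tip_partials))

    # -- evaluation ----------------------------------------------------
    def loglik(self, tree: TimeTree, clock_rate: float = 1.0,
               char_rates: Optional[Sequence[float]] = None) -> float:
        """Log-likelihood of the alignment on ``tree``.

        Branch expected substitutions are duration x ``clock_rate`` x the
        node's relaxed-clock multiplier x the character's partition rate.
        ``char_rates`` overrides the per-character rates given at
        construction (tip partials are rate-independent, so engines need
        not be rebuilt when rates move).
        """
        tree_taxa = set(tree.tip_labels())
        if tree_taxa != set(self.matrix.taxa):
            raise ValueError(
                f"tree/alignment taxon mismatch: {sorted(tree_taxa ^ set(self.matrix.taxa))}")
        rates = self.default_rates if char_rates is None else np.asarray(
            char_rates, dtype=float)
        total = 0.0
        post = tree.postorder()
        for k, cols, _, tip_partials in self.groups:
            grp_rates = rates[cols]
            total += self._group_loglik(post, tree, k, grp_rates, tip_partials,
                                        clock_rate)
            if self.mkv:
                total -= self._mkv_correction(post, tree, k, grp_rates,
                                              tip_partials, clock_rate)
        return total

    def _branch_d(self, tree: TimeTree, nd: Node, grp_rates: np.ndarray,
                  clock_rate: float) -> np.ndarray:
        return tree.branch_duration(nd) * clock_rate * nd.rate_multiplier * grp_rates

    def _group_loglik(self, post: List[Node], tree: TimeTree, k: int,
                      grp_rates: np.ndarray, tip_partials: Dict[str, np.ndarray],
                      clock_rate: float = 1.0) -> float:
        per_char = self._group_loglik_vec(post, tree, k, grp_rates, tip_partials,
                                          clock_rate)
        return float(per_char.sum())

    def _mkv_correction(self, post: List[Node], tree: TimeTree, k: int,
                        grp_rates: np.ndarray, tip_partials: Dict[str, np.ndarray],
                        clock_rate: float) -> float:
        """log P(character variable) summed over the group (Mkv conditioning)."""
        nchar = len(grp_rates)
        tips = [nd for nd in post if nd.is_tip]
        # likelihood of each constant pattern, per character rate
        p_const = np.zeros(nchar)
        for s in range(k):
            const_partials = {
                t.label: np.tile(np.eye(k)[s], (nchar, 1)) for t in tips}
            ll = self._group_loglik_vec(post, tree, k, grp_rates, const_partials,
                                        clock_rate)
            p_const += np.exp(ll)
        return float(np.sum(np.log1p(-np.minimum(p_const, 1 - 1e-15))))

    def _group_loglik_vec(self, post, tree, k, grp_rates, tip_partials,
                          clock_rate) -> np.ndarray:
        nchar = len(grp_rates)
        partial: Dict[int, np.ndarray] = {}
        logscale = np.zeros(nchar)
        for nd in post:
            if nd.is_tip:
                partial[id(nd)] = tip_partials[nd.label]
                continue
            acc = np.ones((nchar, k))
            for ch in nd.children:
                d = self._branch_d(tree, ch, grp_rates, clock_rate)
                e = np.exp(-k * d / (k - 1))[:, None]
                v = partial.pop(id(ch))
                tot = v.sum(axis=1, keepdims=True)
                acc *= (1.0 - e) / k * tot + e * v
            scale = acc.max(axis=1)
            scale = np.where(scale > 0, scale, 1.0)
            acc /= scale[:, None]
            logscale += np.log(scale)
            partial[id(nd)] = acc
        rootp = partial[id(tree.root)]
        return np.log(rootp.sum(axis=1) / k) + logscale


def pruning_loglik(tree: TimeTree, matrix: MorphMatrix,
                   char_rates: Optional[Sequence[float]] = None,
                   clock_rate: float = 1.0, mkv: bool = False) -> float:
    """One-shot pruning log-likelihood (convenience wrapper)."""
    engine = MkLikelihood(matrix, char_rates, mkv=mkv)
    return engine.loglik(tree, clock_rate)


def char_rates_from_scheme(scheme: PartitionScheme, model: MkPartitionModel) -> np.ndarray:
    """Per-character rate vector implied by a partition scheme and model."""
    return np.array([model.rates[pid] for pid in scheme.assignment])
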