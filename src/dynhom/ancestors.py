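"""Ancestral sequence logging at a focal internal node.

At every logged MCMC sample, a full character-state vector is drawn at
the MRCA of the focal clade from its conditional distribution given the
tip data, the current tree and parameters, under the currently active
homology alignment.  Characters are conditionally independent given the
tree, so drawing each character from its conditional at the single
focal node yields a coherent joint phenotype vector; the set of vectors
across samples forms the credible set of ancestral phenotypes.

The conditional at a node combines the standard "below" partials from
the pruning pass with an "above" pass from the root:

    P(state s at v | data)  proportional to  A_v(s) * L_v(s)

where ``L_v`` is the usual conditional likelihood of the data below
``v`` and ``A_v`` carries the root prior and the data outside ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import INAPPLICABLE, MISSING, MorphMatrix, compose_matrix_multi
from .tree import Node, TimeTree


@dataclass
class AncestorSample:
    """One posterior draw of the focal node's full character vector.

    ``states`` holds the drawn state symbol per composite character, or
    -1 where the character has no observed states at all (the draw is
    then from the model's marginal over an arbitrary binary alphabet and
    carries no information).
    """

    generation: int
    homology: Tuple[int, ...]
    states: List[int]


def _below_partials(tree: TimeTree, tip_partials: Dict[str, np.ndarray],
                    k: int, rates: np.ndarray, clock_rate: float
                    ) -> Dict[int, np.ndarray]:
    partial: Dict[int, np.ndarray] = {}
    nchar = len(rates)
    for nd in tree.postorder():
        if nd.is_tip:
            partial[id(nd)] = tip_partials[nd.label]
            continue
        acc = np.ones((nchar, k))
        for ch in nd.children:
            d = tree.branch_duration(ch) * clock_rate * ch.rate_multiplier * rates
            e = np.exp(-k * d / (k - 1))[:, None]
            v = partial[id(ch)]
            tot = v.sum(axis=1, keepdims=True)
            acc *= (1.0 - e) / k * tot + e * v
        m = acc.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        partial[id(nd)] = acc / m[:, None]
    return partial


def node_state_distributions(tree: TimeTree, matrix: MorphMatrix, node: Node,
                             char_rates: Optional[Sequence[float]] = None,
                             clock_rate: float = 1.0) -> List[np.ndarray]:
    """Conditional state distribution at ``node`` for every character.

    Probabilities are over each character's observed-state alphabet
    (sorted); characters with no observed states get a uniform
    distribution over a nominal binary alphabet.
    """
    rates_all = np.ones(matrix.n_char) if char_rates is None else np.asarray(
        char_rates, dtype=float)
    # group characters by model state count, mirroring the pruning engine
    groups: Dict[int, List[int]] = {}
    for j in range(matrix.n_char):
        k = max(matrix.state_count(j), 2)
        groups.setdefault(k, []).append(j)

    out: List[Optional[np.ndarray]] = [None] * matrix.n_char
    path: List[Node] = []
    nd = node
    while nd is not None:
        path.append(nd)
        nd = nd.parent
    path.reverse()  # root ... node

    for k, cols in groups.items():
        rates = rates_all[np.array(cols)]
        nchar = len(cols)
        tip_partials: Dict[str, np.ndarray] = {}
        for taxon, row in zip(matrix.taxa, matrix.cells):
            part = np.zeros((nchar, k))
            for idx, j in enumerate(cols):
                cell = row[j]
                if cell is MISSING or cell is INAPPLICABLE:
                    part[idx, :] = 1.0
                else:
                    alphabet = sorted(matrix.observed_states(j))
                    for rank, s in enumerate(alphabet):
                        if s in cell:
                            part[idx, rank] = 1.0
                    if not part[idx].any():
                        part[idx, :] = 1.0
            tip_partials[taxon] = part
        below = _below_partials(tree, tip_partials, k, rates, clock_rate)

        above = np.full((nchar, k), 1.0 / k)  # root prior
        for child in path[1:]:
            parent = child.parent
            sib_factor = np.ones((nchar, k))
            for sib in parent.children:
                if sib is child:
                    continue
                d = tree.branch_duration(sib) * clock_rate * \
                    sib.rate_multiplier * rates
                e = np.exp(-k * d / (k - 1))[:, None]
                v = below[id(sib)]
                tot = v.sum(axis=1, keepdims=True)
                sib_factor *= (1.0 - e) / k * tot + e * v
            au = above * sib_factor
            d = tree.branch_duration(child) * clock_rate * \
                child.rate_multiplier * rates
            e = np.exp(-k * d / (k - 1))[:, None]
            tot = au.sum(axis=1, keepdims=True)
            above = (1.0 - e) / k * tot + e * au  # symmetric P: same form
            m = above.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            above /= m[:, None]

        joint = above * below[id(node)]
        joint /= joint.sum(axis=1, keepdims=True)
        for idx, j in enumerate(cols):
            out[j] = joint[idx]
    return out  # type: ignore[return-value]


def sample_ancestral_states(state, focal_clade: Sequence[str],
                            rng: np.random.Generator,
                            generation: int = 0) -> AncestorSample:
    """Joint draw of all composite-character states at the clade's MRCA.

    ``state`` is a :class:`dynhom.mcmc.ModelState`; the composite
    alignment of the currently active homology state(s) is used, and the
    sample records those homology states so downstream distance
    calculations can use the matching alignment.
    """
    tree = state.tree
    if not tree.is_clade(focal_clade):
        raise ValueError("focal clade is not monophyletic in the current tree")
    node = tree.mrca(focal_clade)
    composite = compose_matrix_multi(state.fixed, state.blocks, state.homology)
    dists = node_state_distributions(
        tree, composite, node, state.char_rates(), state.clock.clock_rate)
    states: List[int] = []
    for j, probs in enumerate(dists):
        alphabet = sorted(composite.observed_states(j))
        # pad to the model's state count with unobserved symbols so a
        # draw of an unobserved model state maps to a real symbol
        pad = [s for s in range(10) if s not in alphabet]
        full = alphabet + pad[: len(probs) - len(alphabet)]
        draw = int(rng.choice(len(probs), p=probs))
        if not alphabet:
            states.append(-1)  # no observed states: uninformative draw
        else:
            states.append(full[draw])
    return AncestorSample(generation=generation,
                          homology=tuple(state.homology), states=states)


def ancestral_state_posteriors(samples: Sequence[AncestorSample]
                               ) -> List[Dict[str, object]]:
    """Per-character state frequencies and modal state across samples."""
    if not samples:
        raise ValueError("need at least one ancestor sample")
    n_char = len(samples[0].states)
    out: List[Dict[str, object]] = []
    for j in range(n_char):
        counts: Dict[int, int] = {}
        for s in samples:
            counts[s.states[j]] = counts.get(s.states[j], 0) + 1
        total = sum(counts.values())
        freqs = {st: c / total for st, c in sorted(counts.items())}
        modal = max(sorted(counts), key=lambda st: counts[st])
        out.append({
            "character": j,
            "frequencies": freqs,
            "modal_state": modal,
            "posterior_probability": counts[modal] / total,
        })
    return out
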