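"""Parsimony lengths, homoplasy, and implied-weights heuristic search.

Homoplasy of a character on a tree is its Fitch length minus its minimum
conceivable length (observed states - 1).  The implied-weights score of a
tree is ``sum_c h_c / (h_c + k)`` with concavity constant ``k`` (default
10); lower is better.  The search is a seeded random-addition +
subtree-pruning-regrafting heuristic over rooted binary topologies
(scores are rooting-invariant), used to obtain the per-character
homoplasy values that drive rate partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .matrix import INAPPLICABLE, MISSING, Cell, HomologyBlock, MorphMatrix

FULL_MASK = (1 << 10) - 1  # symbols 0..9


@dataclass
class ParsimonyConfig:
    concavity: float = 10.0
    n_random_addition_starts: int = 10
    spr_rounds: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concavity <= 0:
            raise ValueError("concavity constant k must be positive")


@dataclass
class SearchResult:
    newick: str
    score: float
    homoplasy: np.ndarray
    steps: np.ndarray


def _cell_mask(cell: Cell) -> int:
    if cell is MISSING or cell is INAPPLICABLE:
        return FULL_MASK
    mask = 0
    for s in cell:
        mask |= 1 << s
    return mask


def tip_masks(matrix: MorphMatrix) -> np.ndarray:
    """(n_taxa, n_char) bitmask array; missing/inapplicable = full alphabet."""
    out = np.empty((matrix.n_taxa, matrix.n_char), dtype=np.int64)
    for i, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            out[i, j] = _cell_mask(cell)
    return out


# ---------------------------------------------------------------------------
# Mutable rooted binary tree for the search
# ---------------------------------------------------------------------------

class _Tree:
    """Rooted binary tree over tips ``0..n-1``; internal nodes allocated above.

    The arrays are sized for n tips + n-1 internal nodes; ``parent``,
    ``left`` and ``right`` use -1 as "none".
    """

    def __init__(self, n_tips: int):
        size = 2 * n_tips - 1
        self.n_tips = n_tips
        self.parent = np.full(size, -1, dtype=np.int64)
        self.left = np.full(size, -1, dtype=np.int64)
        self.right = np.full(size, -1, dtype=np.int64)
        self.in_tree = np.zeros(size, dtype=bool)
        self.root = -1
        self._free: List[int] = list(range(2 * n_tips - 2, n_tips - 1, -1))

    def init_three(self, a: int, b: int, c: int) -> None:
        x = self._free.pop()
        r = self._free.pop()
        self.left[x], self.right[x] = b, c
        self.parent[b] = self.parent[c] = x
        self.left[r], self.right[r] = a, x
        self.parent[a] = self.parent[x] = r
        self.parent[r] = -1
        self.root = r
        for nd in (a, b, c, x, r):
            self.in_tree[nd] = True

    def _replace_child(self, p: int, old: int, new: int) -> None:
        if self.left[p] == old:
            self.left[p] = new
        else:
            self.right[p] = new

    def insert_on_edge(self, sub: int, u: int) -> int:
        """Attach subtree ``sub`` on the edge above ``u`` (or above the
        root when ``u`` is the root); returns the created node."""
        x = self._free.pop()
        self.in_tree[x] = True
        pu = self.parent[u]
        self.left[x], self.right[x] = u, sub
        self.parent[u] = self.parent[sub] = x
        self.parent[x] = pu
        if pu == -1:
            self.root = x
        else:
            self._replace_child(pu, u, x)
        return x

    def detach(self, sub: int) -> int:
        """Remove the subtree rooted at ``sub``; returns its former sibling."""
        p = self.parent[sub]
        sib = self.right[p] if self.left[p] == sub else self.left[p]
        g = self.parent[p]
        self.parent[sib] = g
        if g == -1:
            self.root = sib
        else:
            self._replace_child(g, p, sib)
        self.in_tree[p] = False
        self.parent[sub] = -1
        self.parent[p] = self.left[p] = self.right[p] = -1
        self._free.append(p)
        return sib

    def postorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            if self.left[nd] != -1:
                stack.append(self.left[nd])
                stack.append(self.right[nd])
        order.reverse()
        return order

    def nodes_in_subtree(self, v: int) -> List[int]:
        out = [v]
        stack = [v]
        while stack:
            nd = stack.pop()
            if self.left[nd] != -1:
                for ch in (self.left[nd], self.right[nd]):
                    out.append(ch)
                    stack.append(ch)
        return out

    def present_nodes(self) -> List[int]:
        return [i for i in range(len(self.parent)) if self.in_tree[i]]

    def newick(self, labels: Sequence[str]) -> str:
        def rec(nd: int) -> str:
            if self.left[nd] == -1:
                return labels[nd]
            return f"({rec(self.left[nd])},{rec(self.right[nd])})"

        return rec(self.root) + ";"


def _fitch_on_tree(tree: _Tree, masks: np.ndarray) -> np.ndarray:
    """Per-character Fitch steps for the current tree state."""
    n_char = masks.shape[1]
    size = len(tree.parent)
    S = np.zeros((size, n_char), dtype=np.int64)
    steps = np.zeros(n_char, dtype=np.int64)
    for nd in tree.postorder():
        if tree.left[nd] == -1:
            S[nd] = masks[nd]
        else:
            a = S[tree.left[nd]]
            b = S[tree.right[nd]]
            inter = a & b
            empty = inter == 0
            steps += empty
            S[nd] = np.where(empty, a | b, inter)
    return steps


# ---------------------------------------------------------------------------
# Friendly single-character / single-tree API
# ---------------------------------------------------------------------------

TreeLike = Union[str, tuple, "_LabelledTree"]


class _LabelledTree:
    """Fixed topology with named tips (parsed once, scored many times)."""

    def __init__(self, tree: _Tree, labels: List[str]):
        self.tree = tree
        self.labels = labels

    @classmethod
    def parse(cls, source: TreeLike) -> "_LabelledTree":
        if isinstance(source, _LabelledTree):
            return source
        if isinstance(source, str):
            nested = _newick_to_nested(source)
        else:
            nested = source
        labels: List[str] = []
        _collect_labels(nested, labels)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")
        if len(labels) < 2:
            raise ValueError("tree needs at least 2 tips")
        index = {lab: i for i, lab in enumerate(labels)}
        tree = _Tree(max(len(labels), 2))
        if len(labels) == 2:
            # degenerate cherry
            x = tree._free.pop()
            tree.left[x], tree.right[x] = 0, 1
            tree.parent[0] = tree.parent[1] = x
            tree.root = x
            tree.in_tree[[0, 1, x]] = True
        else:
            _build_from_nested(tree, nested, index)
        return cls(tree, labels)


def _newick_to_nested(newick: str):
    text = newick.strip().rstrip(";")
    pos = 0

    def parse() -> object:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            if text[pos] != ")":
                raise ValueError(f"bad newick near position {pos}")
            pos += 1
            # strip any label/branch-length after ')'
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            return tuple(children)
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        label = text[start:pos].split(":")[0].strip()
        return label

    out = parse()
    if pos != len(text):
        raise ValueError("trailing characters in newick string")
    return out


def _collect_labels(nested, out: List[str]) -> None:
    if isinstance(nested, tuple):
        for child in nested:
            _collect_labels(child, out)
    else:
        out.append(str(nested))


def _build_from_nested(tree: _Tree, nested, index: Dict[str, int]) -> int:
    def rec(node) -> int:
        if not isinstance(node, tuple):
            return index[str(node)]
        kids = [rec(ch) for ch in node]
        # resolve polytomies left-to-right (steps depend on resolution only
        # for multifurcations, which callers should avoid for exact counts)
        cur = kids[0]
        for nxt in kids[1:]:
            x = tree._free.pop()
            tree.in_tree[x] = True
            tree.left[x], tree.right[x] = cur, nxt
            tree.parent[cur] = tree.parent[nxt] = x
            cur = x
        return cur

    root = rec(nested)
    tree.parent[root] = -1
    tree.root = root
    tree.in_tree[[i for i in index.values()]] = True
    return root


def _character_masks(lt: _LabelledTree, character: Dict[str, Cell]) -> np.ndarray:
    masks = np.empty((lt.tree.n_tips, 1), dtype=np.int64)
    for lab in lt.labels:
        if lab not in character:
            raise ValueError(f"tip {lab!r} absent from character")
    for i, lab in enumerate(lt.labels):
        cell = character[lab]
        if isinstance(cell, int):
            cell = frozenset({cell})
        masks[i, 0] = _cell_mask(cell)
    return masks


def fitch_steps(tree: TreeLike, character: Dict[str, Cell]) -> int:
    """Minimum unordered changes of one character on a fixed topology."""
    lt = _LabelledTree.parse(tree)
    return int(_fitch_on_tree(lt.tree, _character_masks(lt, character))[0])


def observed_state_count(character: Dict[str, Cell]) -> int:
    seen: set = set()
    for cell in character.values():
        if isinstance(cell, int):
            seen.add(cell)
        elif isinstance(cell, frozenset):
            seen |= cell
    return len(seen)


def homoplasy(tree: TreeLike, character: Dict[str, Cell]) -> int:
    """Extra steps beyond the character's minimum (observed states - 1)."""
    steps = fitch_steps(tree, character)
    m = max(observed_state_count(character) - 1, 0)
    return max(steps - m, 0)


def _matrix_character(matrix: MorphMatrix, j: int) -> Dict[str, Cell]:
    return {t: row[j] for t, row in zip(matrix.taxa, matrix.cells)}


def fitch_steps_matrix(tree: TreeLike, matrix: MorphMatrix) -> np.ndarray:
    """Per-character Fitch steps, vectorised across the matrix."""
    lt = _LabelledTree.parse(tree)
    order = [matrix.taxa.index(lab) for lab in lt.labels]
    masks = tip_masks(matrix)[order]
    return _fitch_on_tree(lt.tree, masks)


def homoplasy_vector(tree: TreeLike, matrix: MorphMatrix) -> np.ndarray:
    steps = fitch_steps_matrix(tree, matrix)
    mins = np.array([max(matrix.state_count(j) - 1, 0) for j in range(matrix.n_char)])
    return np.maximum(steps - mins, 0)


def implied_weights_score(tree: TreeLike, matrix: MorphMatrix, k: float = 10.0) -> float:
    """Goloboff fit cost sum h/(h+k); lower is better."""
    if k <= 0:
        raise ValueError("concavity constant k must be positive")
    h = homoplasy_vector(tree, matrix)
    return float(np.sum(h / (h + k)))


def homology_min_homoplasy(block: HomologyBlock,
                           vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise minimum homoplasy across a block's homology states.

    A character whose homoplasy depends on the homology state is assigned
    the lower value.
    """
    if len(vectors) != block.state_count:
        raise ValueError("one homoplasy vector per homology state required")
    lengths = {len(v) for v in vectors}
    if lengths != {block.n_char}:
        raise ValueError("homoplasy vector length mismatch with block width")
    stacked = np.vstack([np.asarray(v) for v in vectors])
    return stacked.min(axis=0)


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------

def _score_steps(steps: np.ndarray, mins: np.ndarray, k: float) -> float:
    h = np.maximum(steps - mins, 0)
    return float(np.sum(h / (h + k)))


def _random_addition_tree(masks: np.ndarray, mins: np.ndarray, k: float,
                          rng: np.random.Generator) -> _Tree:
    n = masks.shape[0]
    order = rng.permutation(n)
    tree = _Tree(n)
    tree.init_three(int(order[0]), int(order[1]), int(order[2]))
    for tip in order[3:]:
        tip = int(tip)
        tree.in_tree[tip] = True
        best: Tuple[float, int] = (np.inf, -1)
        candidates = [nd for nd in tree.present_nodes() if nd != tip]
        for u in candidates:
            x = tree.insert_on_edge(tip, u)
            score = _score_steps(_fitch_on_tree(tree, masks), mins, k)
            tree.detach(tip)
            if score < best[0] - 1e-12:
                best = (score, u)
        tree.insert_on_edge(tip, best[1])
    return tree


def _spr_improve(tree: _Tree, masks: np.ndarray, mins: np.ndarray, k: float,
                 max_rounds: int) -> float:
    best = _score_steps(_fitch_on_tree(tree, masks), mins, k)
    for _ in range(max_rounds):
        improved = False
        for v in list(tree.present_nodes()):
            if v == tree.root or tree.parent[v] == -1:
                continue
            sub_nodes = set(tree.nodes_in_subtree(v))
            if len(sub_nodes) >= 2 * tree.n_tips - 3:
                continue
            old_sib = tree.detach(v)
            found = None
            for u in tree.present_nodes():
                if u in sub_nodes:
                    continue
                tree.insert_on_edge(v, u)
                score = _score_steps(_fitch_on_tree(tree, masks), mins, k)
                tree.detach(v)
                if score < best - 1e-12:
                    best = score
                    found = u
                    break
            tree.insert_on_edge(v, found if found is not None else old_sib)
            if found is not None:
                improved = True
        if not improved:
            break
    return best


def implied_weights_search(matrix: MorphMatrix,
                           config: Optional[ParsimonyConfig] = None) -> SearchResult:
    """Best-found tree under implied weights; deterministic per seed.

    Runs ``n_random_addition_starts`` greedy random-addition builds, each
    refined by SPR, and returns the lowest-cost topology together with
    every character's homoplasy on it.
    """
    config = config or ParsimonyConfig()
    if matrix.n_taxa < 4:
        raise ValueError("implied-weights search needs at least 4 taxa")
    rng = np.random.default_rng(config.seed)
    masks = tip_masks(matrix)
    mins = np.array([max(matrix.state_count(j) - 1, 0) for j in range(matrix.n_char)])
    best_tree: Optional[_Tree] = None
    best_score = np.inf
    for _ in range(config.n_random_addition_starts):
        tree = _random_addition_tree(masks, mins, config.concavity, rng)
        score = _spr_improve(tree, masks, mins, config.concavity, config.spr_rounds)
        if score < best_score - 1e-12:
            best_score = score
            best_tree = tree
    assert best_tree is not None
    steps = _fitch_on_tree(best_tree, masks)
    hvec = np.maximum(steps - mins, 0)
    return SearchResult(
        newick=best_tree.newick(matrix.taxa),
        score=best_score,
        homoplasy=hvec,
        steps=steps,
    )


def exhaustive_search(matrix: MorphMatrix, k: float = 10.0) -> Tuple[str, float]:
    """Exact implied-weights optimum by enumerating all rooted topologies.

    Feasible for <= 7 taxa; used as an oracle for the heuristic search.
    """
    n = matrix.n_taxa
    if n > 7:
        raise ValueError("exhaustive search limited to 7 taxa")
    labels = matrix.taxa

    def topologies(tips: List[str]):
        if len(tips) == 1:
            yield tips[0]
            return
        first, rest = tips[0], tips[1:]
        for sub in topologies(rest):
            for placed in _insert_everywhere(sub, first):
                yield placed

    def _insert_everywhere(topo, tip):
        yield (topo, tip)
        if isinstance(topo, tuple):
            a, b = topo
            for na in _insert_everywhere(a, tip):
                yield (na, b)
            for nb in _insert_everywhere(b, tip):
                yield (a, nb)

    best = (np.inf, None)
    seen = set()
    for topo in topologies(labels):
        key = _canon(topo)
        if key in seen:
            continue
        seen.add(key)
        score = implied_weights_score(topo, matrix, k)
        if score < best[0] - 1e-12:
            best = (score, topo)
    return _nested_to_newick(best[1]), best[0]


def _canon(topo):
    if isinstance(topo, tuple):
        kids = sorted((_canon(c) for c in topo), key=repr)
        return ("(", tuple(kids), ")")
    return topo


def _nested_to_newick(topo) -> str:
    def rec(t):
        if isinstance(t, tuple):
            return "(" + ",".join(rec(c) for c in t) + ")"
        return str(t)

    return rec(topo) + ";"
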