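"""Rooted, dated trees permitting sampled ancestors.

Node ages are in Ma before present and increase rootward.  A sampled
ancestor is represented as a zero-length terminal attachment: the
sampled taxon is a tip whose pendant branch has zero duration (its
parent sits at exactly the tip's age), so the tree stays strictly
binary and the pruning algorithm needs no special casing.
"""

from __future__ import annotations

from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np

SA_EPS = 1e-9


class Node:
    __slots__ = ("parent", "children", "age", "label", "rate_multiplier")

    def __init__(self, label: Optional[str] = None, age: float = 0.0):
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []
        self.age = float(age)
        self.label = label
        #: relaxed-clock branch-rate multiplier for the branch above this node
        self.rate_multiplier = 1.0

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label or 'internal'}, age={self.age:.3g})"


class TimeTree:
    """Binary rooted time tree with labelled tips."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------
    def postorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        out.reverse()
        return out

    def preorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(reversed(nd.children))
        return out

    def tips(self) -> List[Node]:
        return [nd for nd in self.postorder() if nd.is_tip]

    def internals(self) -> List[Node]:
        return [nd for nd in self.postorder() if nd.children]

    def tip_labels(self) -> List[str]:
        return [nd.label for nd in self.tips()]

    def find_tip(self, label: str) -> Node:
        for nd in self.tips():
            if nd.label == label:
                return nd
        raise KeyError(f"tip {label!r} not in tree")

    # -- structure queries ----------------------------------------------
    def is_sampled_ancestor(self, tip: Node) -> bool:
        return tip.is_tip and tip.parent is not None and \
            (tip.parent.age - tip.age) <= SA_EPS

    def sampled_ancestors(self) -> List[Node]:
        return [t for t in self.tips() if self.is_sampled_ancestor(t)]

    def branch_duration(self, nd: Node) -> float:
        if nd.parent is None:
            return 0.0
        return nd.parent.age - nd.age

    def clade_sets(self) -> Dict[int, FrozenSet[str]]:
        """Tip-label set below each node, keyed by id(node)."""
        out: Dict[int, FrozenSet[str]] = {}
        for nd in self.postorder():
            if nd.is_tip:
                out[id(nd)] = frozenset({nd.label})
            else:
                acc: FrozenSet[str] = frozenset()
                for ch in nd.children:
                    acc |= out[id(ch)]
                out[id(nd)] = acc
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        target = frozenset(labels)
        tips = {t.label for t in self.tips()}
        unknown = target - tips
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        sets = self.clade_sets()
        best: Optional[Node] = None
        for nd in self.postorder():
            if target <= sets[id(nd)]:
                if best is None or len(sets[id(nd)]) < len(sets[id(best)]):
                    best = nd
        assert best is not None
        return best

    def is_clade(self, labels: Iterable[str]) -> bool:
        target = frozenset(labels)
        node = self.mrca(target)
        return self.clade_sets()[id(node)] == target

    def validate(self) -> None:
        """Raise if parent/child pointers or age ordering are inconsistent."""
        for nd in self.postorder():
            for ch in nd.children:
                if ch.parent is not nd:
                    raise AssertionError("broken parent pointer")
                if nd.age < ch.age - SA_EPS:
                    raise AssertionError(
                        f"parent younger than child: {nd.age} < {ch.age}")
            if nd.children and len(nd.children) != 2:
                raise AssertionError("tree must be binary")

    # -- copying ---------------------------------------------------------
    def copy(self) -> "TimeTree":
        mapping: Dict[int, Node] = {}
        for nd in self.postorder():
            new = Node(nd.label, nd.age)
            new.rate_multiplier = nd.rate_multiplier
            mapping[id(nd)] = new
            for ch in nd.children:
                c = mapping[id(ch)]
                c.parent = new
                new.children.append(c)
        return TimeTree(mapping[id(self.root)])

    # -- serialisation ----------------------------------------------------
    def newick(self, include_ages: bool = True, fmt: str = "%.6g") -> str:
        def rec(nd: Node) -> str:
            if nd.is_tip:
                core = _quote(nd.label)
            else:
                core = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if include_ages and nd.parent is not None:
                return core + ":" + fmt % max(self.branch_duration(nd), 0.0)
            return core

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str,
                    tip_ages: Optional[Dict[str, float]] = None) -> "TimeTree":
        """Parse a newick string; node ages from branch lengths.

        Depths are converted to ages by anchoring the deepest tip at its
        given age (default 0).  ``tip_ages``, when provided, overrides
        tip ages directly (branch lengths then only set internal ages
        relative to the root).
        """
        root, _ = _parse_newick(text)
        # compute depths
        depth: Dict[int, float] = {id(root): 0.0}
        tree = cls(root)
        maxdepth = 0.0
        for nd in tree.preorder():
            if nd.parent is not None:
                depth[id(nd)] = depth[id(nd.parent)] + nd.age  # age temp = blen
            maxdepth = max(maxdepth, depth[id(nd)])
        offset = 0.0
        if tip_ages:
            # anchor using the first tip with a given age
            for nd in tree.tips():
                if nd.label in tip_ages:
                    offset = tip_ages[nd.label] - (maxdepth - depth[id(nd)])
                    break
        for nd in tree.postorder():
            nd.age = maxdepth - depth[id(nd)] + offset
        if tip_ages:
            for nd in tree.tips():
                if nd.label in tip_ages:
                    nd.age = tip_ages[nd.label]
        tree.validate()
        return tree


def _quote(label: str) -> str:
    if any(c in label for c in " (),:;"):
        return "'" + label + "'"
    return label


def _parse_newick(text: str):
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> Node:
        nonlocal pos
        nd = Node()
        if text[pos] == "(":
            pos += 1
            nd.children.append(parse())
            while text[pos] == ",":
                pos += 1
                nd.children.append(parse())
            if text[pos] != ")":
                raise ValueError(f"bad newick at {pos}")
            pos += 1
            for ch in nd.children:
                ch.parent = nd
        # label and branch length
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        token = text[start:pos]
        if token:
            if ":" in token:
                label, blen = token.split(":", 1)
                nd.age = float(blen)  # temporarily store branch length
            else:
                label = token
            label = label.strip().strip("'")
            if label and nd.is_tip:
                nd.label = label
        return nd

    root = parse()
    if pos != len(text):
        raise ValueError("trailing characters in newick")
    blen_root = root.age
    root.age = 0.0 if blen_root else 0.0
    return root, None


# ---------------------------------------------------------------------------
# Construction of prior-compatible starting trees
# ---------------------------------------------------------------------------

def build_initial_tree(tip_ages: Dict[str, float],
                       constraints: Sequence[FrozenSet[str]] = (),
                       rng: Optional[np.random.Generator] = None,
                       mean_step: float = 5.0) -> TimeTree:
    """Random starting tree honouring monophyly constraints.

    Constraint sets are clustered first (smallest first, so nested
    constraints compose); internal ages are stacked above the oldest
    descendant with exponential increments of mean ``mean_step`` Myr.
    """
    rng = rng or np.random.default_rng(0)
    groups: List[Node] = [Node(lab, age) for lab, age in tip_ages.items()]

    def join(nodes: List[Node]) -> Node:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            parent = Node(age=max(a.age, b.age) + rng.exponential(mean_step) + 1e-6)
            parent.children = [a, b]
            a.parent = b.parent = parent
            nodes.append(parent)
        return nodes[0]

    labels_of: Callable[[Node], FrozenSet[str]] = lambda nd: frozenset(
        t.label for t in TimeTree(nd).tips())

    for constraint in sorted(constraints, key=len):
        members = [nd for nd in groups if labels_of(nd) <= constraint]
        covered = frozenset().union(*(labels_of(nd) for nd in members)) if members else frozenset()
        if covered != constraint:
            raise ValueError(f"constraint {sorted(constraint)} conflicts with earlier grouping")
        if len(members) > 1:
            for nd in members:
                groups.remove(nd)
            groups.append(join(members))
    root = join(groups)
    tree = TimeTree(root)
    tree.validate()
    return tree
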