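"""Phenetic analysis: MORD distances, principal coordinates, nearest taxa.

The Maximum Observable Rescaled Distance between two rows is the summed
per-character dissimilarity over mutually scored characters divided by
the summed maximum possible dissimilarity over those characters.  With
unordered characters the per-character dissimilarity is a 0/1 mismatch
with maximum 1, so MORD reduces to the Gower coefficient.  Polymorphic
cells count as matching when their state sets intersect (polymorphism
read as uncertainty); a strict-mismatch variant is available.

Principal coordinates analysis is classical metric scaling: eigenvalues
and vectors of the double-centred matrix of -0.5 * D^2, with coordinates
on the positive-eigenvalue axes; negative eigenvalues are reported, and
an optional Cailliez correction makes the distances Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import INAPPLICABLE, MISSING, Cell, MorphMatrix


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no mutually scored characters."""


def _scored(cell: Cell) -> bool:
    return isinstance(cell, frozenset)


def mord_distance(row_a: Sequence[Cell], row_b: Sequence[Cell],
                  strict_polymorphism: bool = False) -> float:
    """MORD / Gower distance between two equal-length rows in [0, 1]."""
    d, n = mord_distance_with_count(row_a, row_b, strict_polymorphism)
    if n == 0:
        raise UndefinedDistanceError("no mutually scored characters")
    return d


def mord_distance_with_count(row_a: Sequence[Cell], row_b: Sequence[Cell],
                             strict_polymorphism: bool = False
                             ) -> Tuple[float, int]:
    """(distance, number of comparable characters); distance NaN if none."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    diff = 0
    comparable = 0
    for a, b in zip(row_a, row_b):
        if not (_scored(a) and _scored(b)):
            continue
        comparable += 1
        if strict_polymorphism:
            mismatch = a != b
        else:
            mismatch = not (a & b)
        diff += int(mismatch)
    if comparable == 0:
        return float("nan"), 0
    return diff / comparable, comparable


@dataclass
class DistanceMatrix:
    labels: List[str]
    distances: np.ndarray           # symmetric, zero diagonal, NaN undefined
    n_comparable: np.ndarray

    def undefined_pairs(self) -> List[Tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.distances[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "label_a": self.labels[i],
                    "label_b": self.labels[j],
                    "distance": self.distances[i, j],
                    "n_comparable": int(self.n_comparable[i, j]),
                })
        return pd.DataFrame(rows)


def distance_matrix(rows: Sequence[Sequence[Cell]], labels: Sequence[str],
                    strict_polymorphism: bool = False) -> DistanceMatrix:
    n = len(rows)
    if len(labels) != n:
        raise ValueError("one label per row required")
    D = np.zeros((n, n))
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d, c = mord_distance_with_count(rows[i], rows[j],
                                            strict_polymorphism)
            D[i, j] = D[j, i] = d
            C[i, j] = C[j, i] = c
    return DistanceMatrix(labels=list(labels), distances=D, n_comparable=C)


def matrix_distance(matrix: MorphMatrix,
                    strict_polymorphism: bool = False) -> DistanceMatrix:
    return distance_matrix(matrix.cells, matrix.taxa, strict_polymorphism)


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class PcoResult:
    labels: List[str]
    coordinates: np.ndarray          # n x n_positive_axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (incl. neg.)
    explained: np.ndarray            # fraction of sum of positive eigenvalues
    correction_constant: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis_{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"label": self.labels, **cols})


def _double_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest constant c such that D + c (off-diagonal) is Euclidean."""
    n = D.shape[0]
    A1 = _double_center_raw(-0.5 * D ** 2)
    A2 = _double_center_raw(-0.5 * D)
    zero = np.zeros((n, n))
    top = np.hstack([zero, 2.0 * A1])
    bottom = np.hstack([-np.eye(n), -4.0 * A2])
    M = np.vstack([top, bottom])
    eig = np.linalg.eigvals(M)
    c = float(np.max(eig.real))
    return max(c, 0.0)


def _double_center_raw(A: np.ndarray) -> np.ndarray:
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def pco(dist: DistanceMatrix, correction: str = "none",
        tol: float = 1e-9) -> PcoResult:
    """Classical metric scaling of a distance matrix.

    Coordinates span the positive-eigenvalue axes (eigenvector scaled by
    the square root of its eigenvalue); all eigenvalues, including
    negative ones, are reported, with variance explained relative to the
    positive part.
    """
    undef = dist.undefined_pairs()
    if undef:
        raise UndefinedDistanceError(
            f"undefined distances for pairs: {undef[:5]}")
    D = dist.distances.astype(float)
    c = 0.0
    if correction == "cailliez":
        c = cailliez_constant(D)
        if c > 0:
            D = D + c
            np.fill_diagonal(D, 0.0)
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'cailliez'")
    B = _double_center(D)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    explained = np.where(vals > 0, vals / pos_sum, 0.0) if pos_sum > 0 else \
        np.zeros_like(vals)
    return PcoResult(labels=list(dist.labels), coordinates=coords,
                     eigenvalues=vals, explained=explained,
                     correction_constant=c)


# ---------------------------------------------------------------------------
# Nearest taxon to a reconstructed ancestor
# ---------------------------------------------------------------------------

@dataclass
class NearestResult:
    label: str
    distance: float
    tied: bool


def ancestor_row(states: Sequence[int]) -> List[Cell]:
    """Convert a drawn ancestral state vector to a matrix row (-1 -> MISSING)."""
    return [MISSING if s < 0 else frozenset({int(s)}) for s in states]


def nearest_taxon(ancestor: Sequence[Cell], matrix: MorphMatrix,
                  strict_polymorphism: bool = False) -> NearestResult:
    """Taxon with the smallest MORD distance to the ancestor row.

    Ties break deterministically by taxon order and are flagged.
    """
    best: Optional[NearestResult] = None
    best_d = np.inf
    tied = False
    for taxon, row in zip(matrix.taxa, matrix.cells):
        d, c = mord_distance_with_count(ancestor, row, strict_polymorphism)
        if c == 0:
            continue
        if d < best_d - 1e-12:
            best = NearestResult(label=taxon, distance=d, tied=False)
            best_d = d
            tied = False
        elif abs(d - best_d) <= 1e-12:
            tied = True
    if best is None:
        raise UndefinedDistanceError(
            "ancestor shares no scored characters with any taxon")
    best.tied = tied
    return best


def subsample_ancestors(samples: Sequence, every: int = 20,
                        modal_only: bool = True) -> Tuple[List, Dict[str, int]]:
    """Ordination subsample of ancestor draws: every ``every``-th retained
    sample, optionally restricted to the modal homology state.

    Returns the subsample and a bookkeeping dict (counts before/after
    exclusion), since the order of thinning versus exclusion changes the
    subsample size by about one and both readings are defensible.
    """
    thinned = list(samples[::every])
    info = {"n_input": len(samples), "n_thinned": len(thinned)}
    if modal_only and thinned:
        from collections import Counter

        modal = Counter(s.homology for s in samples).most_common(1)[0][0]
        thinned = [s for s in thinned if s.homology == modal]
    info["n_final"] = len(thinned)
    return thinned, info
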