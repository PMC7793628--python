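"""Morphological character matrices with dynamic-homology blocks.

A :class:`MorphMatrix` is a taxa-by-characters table of discrete state
sets (subsets of ``0..9``), with distinct tokens for missing (``?``) and
inapplicable (``-``) observations.  A :class:`HomologyBlock` bundles N
alternative codings ("homology alignments") of the same anatomical
features; a composite matrix for homology state ``h`` is the fixed
columns plus coding ``h``.

NEXUS reading is delegated to dendropy; writing uses a small local
serialiser so that polymorphic cells and the missing/inapplicable
distinction round-trip exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import dendropy


class _Token:
    """Singleton sentinel for non-state cells."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Cell recorded as unknown ('?' in NEXUS).
MISSING = _Token("MISSING")
#: Cell recorded as inapplicable ('-' in NEXUS).  Distinct from MISSING in
#: the data model; the likelihood and distance modules treat both as
#: uninformative.
INAPPLICABLE = _Token("INAPPLICABLE")

Cell = Union[frozenset, _Token]


class NexusParseError(ValueError):
    """Raised for malformed NEXUS input (ragged rows, bad symbols...)."""


def _cell_key(cell: Cell) -> tuple:
    if cell is MISSING:
        return (2, ())
    if cell is INAPPLICABLE:
        return (3, ())
    return (1, tuple(sorted(cell)))


@dataclass
class CharMeta:
    ordered: bool = False


@dataclass
class MorphMatrix:
    """Discrete morphological character matrix.

    Parameters
    ----------
    taxa:
        Ordered taxon labels (unique).
    cells:
        One row per taxon; each row a list of cells.  A cell is either a
        non-empty ``frozenset`` of integer states, :data:`MISSING`, or
        :data:`INAPPLICABLE`.
    char_meta:
        Per-character metadata (ordered/unordered flag).
    """

    taxa: List[str]
    cells: List[List[Cell]]
    char_meta: List[CharMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        widths = {len(row) for row in self.cells}
        if len(self.cells) != len(self.taxa) or (widths and len(widths) != 1):
            raise ValueError("ragged matrix: rows must all have the same length")
        if not self.char_meta:
            self.char_meta = [CharMeta() for _ in range(self.n_char)]
        if len(self.char_meta) != self.n_char:
            raise ValueError("char_meta length mismatch")
        for t, row in zip(self.taxa, self.cells):
            for j, cell in enumerate(row):
                if isinstance(cell, frozenset):
                    if not cell:
                        raise ValueError(f"empty state set at {t}, character {j + 1}")
                    if not cell <= set(range(10)):
                        raise ValueError(f"state outside 0-9 at {t}, character {j + 1}")

    # -- basic geometry ------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> List[Cell]:
        return self.cells[self.taxa.index(taxon)]

    def column(self, j: int) -> List[Cell]:
        return [row[j] for row in self.cells]

    # -- per-character summaries --------------------------------------
    def observed_states(self, j: int) -> List[int]:
        """Sorted union of non-missing state sets in column ``j``."""
        seen: set = set()
        for row in self.cells:
            cell = row[j]
            if isinstance(cell, frozenset):
                seen |= cell
        return sorted(seen)

    def state_count(self, j: int) -> int:
        """Observed-state count of column ``j`` (0 if entirely missing)."""
        return len(self.observed_states(j))

    def state_counts(self) -> List[int]:
        return [self.state_count(j) for j in range(self.n_char)]

    # -- column surgery ------------------------------------------------
    def subset_columns(self, columns: Sequence[int]) -> "MorphMatrix":
        return MorphMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in columns] for row in self.cells],
            char_meta=[self.char_meta[j] for j in columns],
        )

    def concat(self, other: "MorphMatrix") -> "MorphMatrix":
        if self.taxa != other.taxa:
            missing = sorted(set(self.taxa) ^ set(other.taxa))
            raise ValueError(f"taxon mismatch between matrices: {missing or 'ordering differs'}")
        return MorphMatrix(
            taxa=list(self.taxa),
            cells=[a + b for a, b in zip(self.cells, other.cells)],
            char_meta=self.char_meta + other.char_meta,
        )

    def equal_cells(self, other: "MorphMatrix") -> bool:
        if self.taxa != other.taxa or self.n_char != other.n_char:
            return False
        for ra, rb in zip(self.cells, other.cells):
            for a, b in zip(ra, rb):
                if _cell_key(a) != _cell_key(b):
                    return False
        return True


@dataclass
class HomologyBlock:
    """N alternative codings of the same character subset.

    Each coding is a :class:`MorphMatrix` over the same taxa with the same
    number of columns; the active coding is selected by an integer
    homology state ``h`` in ``0..N-1``.
    """

    label: str
    codings: List[MorphMatrix]

    def __post_init__(self) -> None:
        if len(self.codings) < 2:
            raise ValueError("a homology block needs at least two codings")
        taxa0 = self.codings[0].taxa
        width0 = self.codings[0].n_char
        for c in self.codings[1:]:
            if c.taxa != taxa0:
                raise ValueError(f"block '{self.label}': codings differ in taxa")
            if c.n_char != width0:
                raise ValueError(f"block '{self.label}': codings differ in character count")

    @property
    def state_count(self) -> int:
        return len(self.codings)

    @property
    def n_char(self) -> int:
        return self.codings[0].n_char


@dataclass
class PartitionScheme:
    """Grouping of characters by (observed-state count, homoplasy) key."""

    assignment: List[int]                      # character index -> partition id
    key: Dict[int, Tuple[int, int]]            # partition id -> (state count, homoplasy)
    weights: Dict[int, int]                    # partition id -> member count

    @property
    def n_partitions(self) -> int:
        return len(self.key)


def partition_characters(state_counts: Sequence[int], homoplasy: Sequence[int]) -> PartitionScheme:
    """Assign each character to the partition of its (states, homoplasy) key.

    Characters sharing both observed-state count and homoplasy value share
    a partition; partition ids are numbered in order of first appearance.
    """
    if len(state_counts) != len(homoplasy):
        raise ValueError("state_counts and homoplasy must have equal length")
    if any(h < 0 for h in homoplasy):
        raise ValueError("homoplasy values must be non-negative")
    key_to_id: Dict[Tuple[int, int], int] = {}
    assignment: List[int] = []
    for s, h in zip(state_counts, homoplasy):
        k = (int(s), int(h))
        if k not in key_to_id:
            key_to_id[k] = len(key_to_id)
        assignment.append(key_to_id[k])
    weights: Dict[int, int] = {}
    for pid in assignment:
        weights[pid] = weights.get(pid, 0) + 1
    return PartitionScheme(
        assignment=assignment,
        key={pid: k for k, pid in key_to_id.items()},
        weights=weights,
    )


def compose_matrix(fixed: MorphMatrix, block: HomologyBlock, h: int) -> MorphMatrix:
    """Composite alignment for homology state ``h``: fixed columns then
    the block's coding ``h`` in declared column order."""
    if not 0 <= h < block.state_count:
        raise ValueError(
            f"homology state {h} out of range for block '{block.label}' "
            f"with {block.state_count} states"
        )
    return fixed.concat(block.codings[h])


def compose_matrix_multi(fixed: MorphMatrix, blocks: Sequence[HomologyBlock],
                         h: Sequence[int]) -> MorphMatrix:
    """Composite alignment over several independent homology blocks."""
    if len(blocks) != len(h):
        raise ValueError("one homology state per block required")
    out = fixed
    for block, hi in zip(blocks, h):
        if not 0 <= hi < block.state_count:
            raise ValueError(f"homology state {hi} out of range for block '{block.label}'")
        out = out.concat(block.codings[hi])
    return out


# ---------------------------------------------------------------------------
# NEXUS I/O
# ---------------------------------------------------------------------------

def read_nexus(path) -> MorphMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`MorphMatrix`.

    '?' maps to MISSING, '-' to INAPPLICABLE, ``{01}``/``(01)`` to a
    polymorphic state set.  Taxon order is preserved.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise NexusParseError(f"cannot parse NEXUS file {path}: {exc}") from exc
    return _from_dendropy(dm)


def read_nexus_string(text: str) -> MorphMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise NexusParseError(f"cannot parse NEXUS data: {exc}") from exc
    return _from_dendropy(dm)


def _from_dendropy(dm: "dendropy.StandardCharacterMatrix") -> MorphMatrix:
    taxa: List[str] = []
    cells: List[List[Cell]] = []
    lengths = set()
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        row: List[Cell] = []
        for state in seq:
            if state.is_gap_state:
                row.append(INAPPLICABLE)
                continue
            if state.symbol == "?":
                row.append(MISSING)
                continue
            if state.symbol is None:  # polymorphic / ambiguous
                members = frozenset(
                    int(ms.symbol) for ms in state.member_states if ms.symbol.isdigit()
                )
                if not members:
                    row.append(MISSING)
                else:
                    row.append(members)
                continue
            if not state.symbol.isdigit():
                raise NexusParseError(
                    f"undeclared symbol {state.symbol!r} for taxon {taxon.label}"
                )
            row.append(frozenset({int(state.symbol)}))
        taxa.append(taxon.label)
        cells.append(row)
        lengths.add(len(row))
    if len(lengths) > 1:
        widths = {t: len(r) for t, r in zip(taxa, cells)}
        common = max(set(widths.values()), key=list(widths.values()).count)
        bad = [t for t, w in widths.items() if w != common]
        raise NexusParseError(f"ragged rows for taxa: {bad}")
    try:
        return MorphMatrix(taxa=taxa, cells=cells)
    except ValueError as exc:
        raise NexusParseError(str(exc)) from exc


def _cell_to_symbol(cell: Cell) -> str:
    if cell is MISSING:
        return "?"
    if cell is INAPPLICABLE:
        return "-"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return "{" + "".join(str(s) for s in sorted(cell)) + "}"


def write_nexus(matrix: MorphMatrix, path=None) -> str:
    """Serialise a matrix to NEXUS; returns the text, optionally writing it."""
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};\n")
    buf.write('FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;\n')
    buf.write("MATRIX\n")
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        label = f"'{taxon}'" if any(c.isspace() for c in taxon) else taxon
        buf.write(label.ljust(width))
        buf.write("".join(_cell_to_symbol(c) for c in row))
        buf.write("\n")
    buf.write(";\nEND;\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def split_homology(matrix: MorphMatrix,
                   block_columns: Dict[str, List[List[int]]]) -> Tuple[MorphMatrix, List[HomologyBlock]]:
    """Split a full matrix into fixed columns and homology blocks.

    ``block_columns`` maps a block label to a list of column-index lists
    (1-based, NEXUS convention), one list per homology state.  All listed
    columns are removed from the fixed matrix; each state's list becomes
    one coding of the block.
    """
    blocks: List[HomologyBlock] = []
    used: set = set()
    for label in block_columns:
        states = block_columns[label]
        codings = []
        for cols in states:
            zero_based = [c - 1 for c in cols]
            for c in zero_based:
                if not 0 <= c < matrix.n_char:
                    raise ValueError(f"block '{label}': column {c + 1} out of range")
                if c in used:
                    raise ValueError(f"block '{label}': column {c + 1} used twice")
                used.add(c)
            codings.append(matrix.subset_columns(zero_based))
        blocks.append(HomologyBlock(label=label, codings=codings))
    fixed_cols = [j for j in range(matrix.n_char) if j not in used]
    return matrix.subset_columns(fixed_cols), blocks
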