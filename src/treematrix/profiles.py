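"""Phylogenetic-profile matrices for a view state.

Every displayed gene-tree tip becomes one matrix row.  A cell for column
``u`` is

* OUTGROUP when the extant species of ``u`` are disjoint from the row's span
  (the extant species under the tip's origin taxon) -- outgroup species carry
  no information about a subfamily and are rendered blank;
* otherwise the *average number of in-paralogs* over the intersection:
  sum of per-species copy counts under the tip divided by the number of
  intersecting species, species lost under the tip contributing 0.  A value
  of exactly 0 is a LOST cell (rendered as a zero on gray); anything else is
  a COUNT.

Arithmetic is exact (``fractions.Fraction``); rendering rounds for display
only.  Multiple families stack over the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Optional

from .model import LEAF, LOSS, GeneNode, SpeciesNode, TreeMatrixError
from .reconcile import leaf_counts
from .view import ViewState, visible_columns, visible_tips


class CellKind(Enum):
    COUNT = "count"
    LOST = "lost"
    OUTGROUP = "outgroup"


@dataclass(frozen=True)
class ProfileCell:
    kind: CellKind
    value: Fraction = Fraction(0)

    @classmethod
    def outgroup(cls) -> "ProfileCell":
        return cls(CellKind.OUTGROUP)

    @classmethod
    def of(cls, value: Fraction) -> "ProfileCell":
        if value < 0:
            raise TreeMatrixError("negative copy number")
        return cls(CellKind.LOST if value == 0 else CellKind.COUNT, value)

    def display(self) -> str:
        """Integers bare, non-integers to 1 decimal, OUTGROUP blank."""
        if self.kind is CellKind.OUTGROUP:
            return ""
        if self.value.denominator == 1:
            return str(self.value.numerator)
        return f"{float(self.value):.1f}"


@dataclass
class ProfileRow:
    tip: GeneNode
    origin_taxon: SpeciesNode
    cells: list[ProfileCell]
    label: str


@dataclass
class ProfileMatrix:
    rows: list[ProfileRow]
    columns: list[SpeciesNode]
    vmax: Fraction

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.columns))


def row_label(tip: GeneNode) -> str:
    """Collapsed nodes show their subfamily label, leaves their gene id,
    losses the lost taxon's name."""
    if tip.event == LOSS:
        return tip.taxon.name if tip.taxon is not None else (tip.label or tip.id)
    return tip.label or tip.id


def profile_row(tip: GeneNode, state: ViewState,
                columns: Optional[list[SpeciesNode]] = None) -> ProfileRow:
    """Profile of one displayed tip over the view's visible columns."""
    if tip.taxon is None:
        raise TreeMatrixError(f"tip {tip.id!r} has no origin taxon")
    stree = state.species_tree
    if columns is None:
        columns = visible_columns(state)
    origin = tip.taxon
    span = stree.leaf_set(origin)
    counts = leaf_counts(tip)
    cells: list[ProfileCell] = []
    for column in columns:
        inter = stree.leaf_set(column) & span
        if not inter:
            cells.append(ProfileCell.outgroup())
        else:
            total = sum(counts.get(s, 0) for s in inter)
            cells.append(ProfileCell.of(Fraction(total, len(inter))))
    return ProfileRow(tip=tip, origin_taxon=origin, cells=cells, label=row_label(tip))


def profile_matrix(state: ViewState) -> ProfileMatrix:
    """Rows = visible tips of every family, stacked in family input order;
    columns = visible species-tree tips; ``vmax`` = max COUNT (for shading)."""
    columns = visible_columns(state)
    rows: list[ProfileRow] = []
    for family in state.families:
        for tip in visible_tips(state, family):
            rows.append(profile_row(tip, state, columns))
    vmax = Fraction(0)
    for row in rows:
        for cell in row.cells:
            if cell.kind is CellKind.COUNT and cell.value > vmax:
                vmax = cell.value
    return ProfileMatrix(rows=rows, columns=columns, vmax=vmax)


def matrix_to_tsv(matrix: ProfileMatrix) -> str:
    """Tab-separated export: LOST as ``0``, OUTGROUP as the empty string.

    COUNT values are written exactly when integral, else as decimals.
    """
    header = ["label", "origin_taxon"] + [c.name for c in matrix.columns]
    lines = ["\t".join(header)]
    for row in matrix.rows:
        cells = []
        for cell in row.cells:
            if cell.kind is CellKind.OUTGROUP:
                cells.append("")
            elif cell.value.denominator == 1:
                cells.append(str(cell.value.numerator))
            else:
                cells.append(repr(float(cell.value)))
        lines.append("\t".join([row.label, row.origin_taxon.name] + cells))
    return "\n".join(lines) + "\n"
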