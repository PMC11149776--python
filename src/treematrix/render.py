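"""Deterministic static rendering.

Tri-panel layout: the species tree on top, the gene tree(s) on the left and
the profile heatmap in the matrix between them -- the species tree drawn
orthogonally to the gene tree, so species-tree tips index matrix columns and
gene-tree tips index matrix rows.

Cell shading is logarithmic, ``log2(1+value)/log2(1+vmax)``, so that a single
lineage-specific expansion darkens its column without washing out the rest of
the matrix.  LOST cells are zeros on a gray background; OUTGROUP cells stay
blank.  Branch thickness grows logarithmically with the collapsed subtree
size.  Emission is a pure function of (state, matrix): repeated runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import DUPLICATION, LOSS, SpeciesNode
from .profiles import CellKind, ProfileMatrix, profile_matrix
from .view import ViewState, displayed_internal_nodes, visible_tips

CELL = 26            # cell edge, px
GENE_PANEL = 180     # width of the gene-tree panel
SPECIES_PANEL = 120  # height of the species-tree panel
LABEL_W = 140        # right-hand label gutter
FAMILY_GAP = 8       # px rule between stacked families
MAX_BRANCH_WIDTH = 6.0

#: default heat ramp endpoint (white -> this color); configurable per call.
DEFAULT_RAMP = "#08306b"
LOST_BG = "#d9d9d9"


def shade(value: float, vmax: float) -> float:
    """Cell darkness in [0, 1]: 0 for zero/LOST, log-scaled otherwise."""
    if value <= 0 or vmax <= 0:
        return 0.0
    return min(1.0, math.log2(1.0 + value) / math.log2(1.0 + vmax))


def branch_width(n_leaves: int, cap: float = MAX_BRANCH_WIDTH) -> float:
    """Branch thickness for a subtree of ``n_leaves`` extant genes."""
    if n_leaves < 1:
        raise ValueError("a subtree has at least one leaf")
    return min(cap, 1.0 + math.log2(n_leaves))


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i:i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def heat_color(intensity: float, ramp: str = DEFAULT_RAMP) -> str:
    """Interpolate white -> ramp endpoint by ``intensity``."""
    r, g, b = _hex_to_rgb(ramp)
    mix = lambda c: round(255 + (c - 255) * intensity)
    return f"#{mix(r):02x}{mix(g):02x}{mix(b):02x}"


@dataclass
class RenderModel:
    """Resolved geometry for one view: everything emit_svg needs."""

    width: float
    height: float
    column_x: dict[str, float]            # species node id -> column center x
    row_y: list[float]                    # per matrix row, center y
    species_nodes: dict[str, tuple[float, float]]   # id -> (x, y)
    species_edges: list[tuple[str, str]]  # (parent id, child id)
    gene_nodes: list[dict] = field(default_factory=list)   # drawn gene-tree nodes
    gene_edges: list[dict] = field(default_factory=list)
    row_labels: list[str] = field(default_factory=list)
    row_taxa: list[str] = field(default_factory=list)      # taxonomic level per row
    family_rules: list[float] = field(default_factory=list)


def layout(state: ViewState, matrix: ProfileMatrix) -> RenderModel:
    """Compute coordinates for the tri-panel layout.

    Columns take their x from visible-column order, rows their y from matrix
    row order; species-tree internals are centered over their children and
    gene-tree internals over their displayed subtrees.  Each row is annotated
    on the right with its origin taxon (the taxonomic level of the subtree).
    """
    n_cols = len(matrix.columns)
    n_rows = len(matrix.rows)
    width = GENE_PANEL + n_cols * CELL + LABEL_W
    height = SPECIES_PANEL + n_rows * CELL + FAMILY_GAP * max(0, len(state.families) - 1)

    column_x = {c.id: GENE_PANEL + (i + 0.5) * CELL for i, c in enumerate(matrix.columns)}

    # species tree above the columns
    species_nodes: dict[str, tuple[float, float]] = {}
    species_edges: list[tuple[str, str]] = []
    shown = {c.id for c in matrix.columns}

    def place_species(node: SpeciesNode, depth: int) -> Optional[float]:
        if node.id in shown:
            x = column_x[node.id]
            species_nodes[node.id] = (x, SPECIES_PANEL - 10)
            return x
        xs = []
        for child in node.children:
            cx = place_species(child, depth + 1)
            if cx is not None:
                xs.append(cx)
                species_edges.append((node.id, child.id))
        if not xs:
            return None
        x = sum(xs) / len(xs)
        y = max(8.0, SPECIES_PANEL - 10 - (_species_height(node)) * 18)
        species_nodes[node.id] = (x, y)
        return x

    def _species_height(node: SpeciesNode) -> int:
        if node.id in shown:
            return 0
        return 1 + max((_species_height(c) for c in node.children), default=0)

    place_species(state.display_root, 0)
    # drop dangling edges to hidden nodes
    species_edges = [(p, c) for p, c in species_edges
                     if p in species_nodes and c in species_nodes]

    # rows: one per matrix row; families stacked with a separating rule
    row_y: list[float] = []
    family_rules: list[float] = []
    gene_nodes: list[dict] = []
    gene_edges: list[dict] = []
    y_cursor = SPECIES_PANEL
    row_index = 0
    for fam_i, family in enumerate(state.families):
        if fam_i > 0:
            family_rules.append(y_cursor + FAMILY_GAP / 2)
            y_cursor += FAMILY_GAP
        tips = visible_tips(state, family)
        cache = state.cache(family)
        tip_pos: dict[str, float] = {}
        for tip in tips:
            y = y_cursor + 0.5 * CELL
            row_y.append(y)
            tip_pos[tip.id] = y
            y_cursor += CELL
            row_index += 1

        collapsed = state.collapsed_genes[family.family_id]
        max_depth = [1]

        def place_gene(node, depth: int) -> float:
            max_depth[0] = max(max_depth[0], depth + 1)
            if node.id in collapsed or node.is_tip:
                y = tip_pos[node.id]
                gene_nodes.append({
                    "id": node.id, "family": family.family_id, "depth": depth,
                    "y": y, "tip": True, "event": node.event,
                    "collapsed": node.id in collapsed and not node.is_tip,
                    "n_leaves": max(1, cache.n_leaves[node.id]),
                })
                return y
            ys = []
            children = sorted(
                node.children,
                key=lambda c: (state.species_tree.preorder_index(c.taxon)
                               if c.taxon is not None else -1,
                               -cache.n_leaves[c.id], c.id))
            for child in children:
                cy = place_gene(child, depth + 1)
                ys.append((child, cy))
            y = sum(v for _, v in ys) / len(ys)
            gene_nodes.append({
                "id": node.id, "family": family.family_id, "depth": depth,
                "y": y, "tip": False, "event": node.event, "collapsed": False,
                "n_leaves": max(1, cache.n_leaves[node.id]),
            })
            for child, cy in ys:
                gene_edges.append({
                    "family": family.family_id, "parent": node.id,
                    "child": child.id, "y0": y, "y1": cy,
                    "depth0": depth, "depth1": depth + 1,
                    "width": branch_width(max(1, cache.n_leaves[child.id])),
                })
            return y

        place_gene(family.root, 0)
        # convert depths to x positions within the gene panel
        span = max(1, max_depth[0])
        for entry in gene_nodes:
            if entry["family"] == family.family_id and "x" not in entry:
                entry["x"] = 10 + entry["depth"] * (GENE_PANEL - 30) / span
        for edge in gene_edges:
            if edge["family"] == family.family_id and "x0" not in edge:
                edge["x0"] = 10 + edge["depth0"] * (GENE_PANEL - 30) / span
                edge["x1"] = 10 + edge["depth1"] * (GENE_PANEL - 30) / span

    row_labels = [row.label for row in matrix.rows]
    row_taxa = [row.origin_taxon.name for row in matrix.rows]
    return RenderModel(width=width, height=height, column_x=column_x,
                       row_y=row_y, species_nodes=species_nodes,
                       species_edges=species_edges, gene_nodes=gene_nodes,
                       gene_edges=gene_edges, row_labels=row_labels,
                       row_taxa=row_taxa, family_rules=family_rules)


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_svg(state: ViewState, matrix: Optional[ProfileMatrix] = None,
               ramp: str = DEFAULT_RAMP) -> str:
    """Build the SVG document as a string (deterministic)."""
    if matrix is None:
        matrix = profile_matrix(state)
    model = layout(state, matrix)
    vmax = float(matrix.vmax) if matrix.vmax else 0.0
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
               f'width="{_fmt(model.width)}" height="{_fmt(model.height)}" '
               f'font-family="monospace" font-size="11">')
    out.append(f'<rect width="{_fmt(model.width)}" height="{_fmt(model.height)}" '
               f'fill="#ffffff"/>')

    # matrix cells
    for ri, row in enumerate(matrix.rows):
        y = model.row_y[ri] - CELL / 2
        for ci, cell in enumerate(row.cells):
            x = model.column_x[matrix.columns[ci].id] - CELL / 2
            if cell.kind is CellKind.OUTGROUP:
                continue
            if cell.kind is CellKind.LOST:
                fill = LOST_BG
                text_fill = "#555555"
            else:
                intensity = shade(float(cell.value), vmax)
                fill = heat_color(intensity, ramp)
                text_fill = "#ffffff" if intensity > 0.55 else "#111111"
            out.append(f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{CELL}" '
                       f'height="{CELL}" fill="{fill}" stroke="#cccccc" '
                       f'stroke-width="0.5"/>')
            out.append(f'<text x="{_fmt(x + CELL / 2)}" y="{_fmt(y + CELL / 2 + 4)}" '
                       f'text-anchor="middle" fill="{text_fill}">'
                       f'{cell.display()}</text>')

    # species tree
    for parent_id, child_id in model.species_edges:
        px, py = model.species_nodes[parent_id]
        cx, cy = model.species_nodes[child_id]
        out.append(f'<path d="M {_fmt(px)} {_fmt(py)} L {_fmt(cx)} {_fmt(py)} '
                   f'L {_fmt(cx)} {_fmt(cy)}" fill="none" stroke="#333333" '
                   f'stroke-width="1"/>')
    for column in matrix.columns:
        x = model.column_x[column.id]
        color = _clade_color(state, column) or "#111111"
        out.append(f'<text x="{_fmt(x)}" y="{_fmt(SPECIES_PANEL - 14)}" '
                   f'text-anchor="start" fill="{color}" transform="rotate(-60 '
                   f'{_fmt(x)} {_fmt(SPECIES_PANEL - 14)})">{_esc(column.name)}</text>')

    # gene trees
    for edge in model.gene_edges:
        out.append(f'<path d="M {_fmt(edge["x0"])} {_fmt(edge["y0"])} '
                   f'L {_fmt(edge["x0"])} {_fmt(edge["y1"])} '
                   f'L {_fmt(edge["x1"])} {_fmt(edge["y1"])}" fill="none" '
                   f'stroke="#333333" stroke-width="{_fmt(edge["width"])}"/>')
    for node in model.gene_nodes:
        x, y = node["x"], node["y"]
        if node["event"] == DUPLICATION and not node["tip"]:
            out.append(f'<rect x="{_fmt(x - 3)}" y="{_fmt(y - 3)}" width="6" '
                       f'height="6" fill="#c0392b"/>')
        elif node["collapsed"]:
            out.append(f'<path d="M {_fmt(x)} {_fmt(y - 4)} L {_fmt(x + 8)} '
                       f'{_fmt(y)} L {_fmt(x)} {_fmt(y + 4)} Z" fill="#555555"/>')
        elif node["event"] == LOSS:
            out.append(f'<text x="{_fmt(x)}" y="{_fmt(y + 3)}" fill="#999999" '
                       f'text-anchor="middle">&#215;</text>')

    # row labels (left of matrix) and taxonomic levels (right gutter)
    for ri, label in enumerate(model.row_labels):
        y = model.row_y[ri]
        out.append(f'<text x="{_fmt(GENE_PANEL - 6)}" y="{_fmt(y + 4)}" '
                   f'text-anchor="end">{_esc(label)}</text>')
        out.append(f'<text x="{_fmt(GENE_PANEL + len(matrix.columns) * CELL + 8)}" '
                   f'y="{_fmt(y + 4)}" fill="#666666">{_esc(model.row_taxa[ri])}</text>')
    for y in model.family_rules:
        out.append(f'<line x1="0" y1="{_fmt(y)}" x2="{_fmt(model.width)}" '
                   f'y2="{_fmt(y)}" stroke="#888888" stroke-width="1" '
                   f'stroke-dasharray="4 3"/>')
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _clade_color(state: ViewState, column: SpeciesNode) -> Optional[str]:
    stree = state.species_tree
    node = column
    while node is not None:
        if node.id in state.clade_colors:
            return state.clade_colors[node.id]
        node = node.parent
    return None


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def serialize_state(state: ViewState) -> dict:
    """JSON-able snapshot of the view (embedded in the HTML output)."""
    matrix = profile_matrix(state)
    return {
        "families": [f.family_id for f in state.families],
        "collapsed_genes": {fid: sorted(ids)
                            for fid, ids in sorted(state.collapsed_genes.items())},
        "collapsed_taxa": sorted(state.collapsed_taxa),
        "depth_limit": state.depth_limit,
        "root_taxon": state.root_taxon.name if state.root_taxon else None,
        "clade_colors": dict(sorted(state.clade_colors.items())),
        "columns": [c.name for c in matrix.columns],
        "rows": [
            {
                "label": row.label,
                "origin_taxon": row.origin_taxon.name,
                "cells": [None if c.kind is CellKind.OUTGROUP else str(c.value)
                          for c in row.cells],
            }
            for row in matrix.rows
        ],
    }


def emit_svg(state: ViewState, path: str | Path,
             matrix: Optional[ProfileMatrix] = None, ramp: str = DEFAULT_RAMP) -> Path:
    path = Path(path)
    path.write_text(render_svg(state, matrix, ramp=ramp))
    return path


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
figure {{ margin: 0; overflow-x: auto; }}
</style>
</head>
<body>
<h1>{title}</h1>
<figure>
{svg}
</figure>
<script type="application/json" id="view-state">
{state_json}
</script>
<script>
/* static snapshot: the serialized view state is embedded above for
   downstream tooling; no network assets are referenced. */
var state = JSON.parse(document.getElementById("view-state").textContent);
document.title = document.title + " (" + state.rows.length + " rows x " +
                 state.columns.length + " columns)";
</script>
</body>
</html>
"""


def render_html(state: ViewState, title: str = "gene family view",
                ramp: str = DEFAULT_RAMP) -> str:
    svg = render_svg(state, ramp=ramp)
    state_json = json.dumps(serialize_state(state), sort_keys=True, indent=1)
    return _HTML_TEMPLATE.format(title=_esc(title), svg=svg.split("\n", 1)[1],
                                 state_json=state_json)


def emit_html(state: ViewState, path: str | Path,
              title: str = "gene family view", ramp: str = DEFAULT_RAMP) -> Path:
    """Write a single self-contained HTML file (no external assets)."""
    path = Path(path)
    path.write_text(render_html(state, title=title, ramp=ramp))
    return path
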