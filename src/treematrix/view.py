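"""The view algebra: which gene nodes and taxa are collapsed.

A :class:`ViewState` holds one or more normalized families over a single
species tree together with the current collapse state.  The named operations
are:

* ``smart_collapse`` -- collapse every maximal duplication-free subtree; the
  result is information-equivalent to the full tree given the species tree,
  because a duplication-free subtree's topology is explicit in the species
  tree;
* ``collapse_all`` -- one profile row per family (the family root);
* ``expand_node`` -- reveal topology until the next duplication nodes, which
  define the child subfamilies; everything else stays collapsed;
* ``collapse_taxon`` / ``auto_collapse_depth`` -- species-tree-side collapse:
  the corresponding gene nodes cascade into the collapsed set and profile
  columns merge (averaging happens in :mod:`treematrix.profiles`).

Invariants maintained after every operation: collapsed gene nodes (and
collapsed taxa) form antichains, and every gene node whose taxon lies inside
a collapsed taxon sits at or below some collapsed gene node (the cascade).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    DUPLICATION,
    LEAF,
    LOSS,
    SPECIATION,
    GeneNode,
    ReconciledFamily,
    SpeciesNode,
    SpeciesTree,
    TreeMatrixError,
)
from .reconcile import leaf_counts


class _FamilyCache:
    """Per-family static lookups computed once at view construction."""

    def __init__(self, family: ReconciledFamily, stree: SpeciesTree) -> None:
        self.family = family
        self.index = family.node_index()
        self.parents = family.parents()
        self.has_dup: dict[str, bool] = {}
        self.n_leaves: dict[str, int] = {}
        order: list[GeneNode] = list(family.nodes())
        for node in reversed(order):
            self.has_dup[node.id] = node.event == DUPLICATION or any(
                self.has_dup[c.id] for c in node.children)
            if node.event == LEAF:
                self.n_leaves[node.id] = 1
            else:
                self.n_leaves[node.id] = sum(self.n_leaves[c.id] for c in node.children)

    def ancestors(self, node_id: str):
        node_id_ = node_id
        while node_id_ in self.parents:
            parent = self.parents[node_id_]
            yield parent
            node_id_ = parent.id


@dataclass
class ViewState:
    families: list[ReconciledFamily]
    species_tree: SpeciesTree
    collapsed_genes: dict[str, set[str]] = field(default_factory=dict)
    collapsed_taxa: set[str] = field(default_factory=set)
    depth_limit: Optional[int] = None
    root_taxon: Optional[SpeciesNode] = None
    clade_colors: dict[str, str] = field(default_factory=dict)
    _caches: dict[str, _FamilyCache] = field(default_factory=dict, repr=False)

    def cache(self, family: ReconciledFamily) -> _FamilyCache:
        return self._caches[family.family_id]

    @property
    def display_root(self) -> SpeciesNode:
        return self.root_taxon or self.species_tree.root


def init_view(families: list[ReconciledFamily], stree: SpeciesTree,
              root_taxon: Optional[str] = None) -> ViewState:
    """Build a view with empty collapse sets.

    With ``root_taxon`` the display is restricted to that species-tree
    subtree: families are pruned to gene nodes whose taxon lies within it
    (loss tips outside are dropped, taxa above are clamped) and the columns
    are restricted accordingly.
    """
    if not families:
        raise TreeMatrixError("a view needs at least one family")
    for family in families:
        if family.species_tree is not stree:
            raise TreeMatrixError(
                f"family {family.family_id!r} is attached to a different species tree")
    root_node = stree.resolve(root_taxon) if root_taxon else None
    if root_node is not None:
        families = [prune_to_taxon(f, root_node) for f in families]
        families = [f for f in families if f.root is not None]
        if not families:
            raise TreeMatrixError(f"no family has genes within taxon {root_taxon!r}")
    state = ViewState(families=families, species_tree=stree, root_taxon=root_node)
    seen: set[str] = set()
    for family in families:
        if family.family_id in seen:
            raise TreeMatrixError(f"duplicate family id {family.family_id!r}")
        seen.add(family.family_id)
        state.collapsed_genes[family.family_id] = set()
        state._caches[family.family_id] = _FamilyCache(family, stree)
    return state


def prune_to_taxon(family: ReconciledFamily, taxon: SpeciesNode) -> ReconciledFamily:
    """Restrict a normalized family to the subtree of ``taxon``.

    Gene nodes whose taxon is disjoint from the subtree (including loss tips
    of outside clades) are removed; nodes at strict ancestors of ``taxon``
    are clamped to it, and speciation chains made unary by the pruning are
    contracted.
    """
    stree = family.species_tree

    def rebuild(node: GeneNode) -> Optional[GeneNode]:
        within = stree.is_ancestor_or_self(taxon, node.taxon)
        above = stree.is_ancestor_or_self(node.taxon, taxon) and not within
        if not within and not above:
            return None
        if node.is_tip:
            if not within:  # a loss at a strict ancestor spans outside taxa too
                return None
            return GeneNode(node.id, node.event, node.taxon, node.species,
                            node.label, [], dict(node.extras))
        children = [c2 for c in node.children if (c2 := rebuild(c)) is not None]
        if not children:
            return None
        new_taxon = node.taxon if within else taxon
        if node.event == SPECIATION and len(children) == 1 \
                and children[0].taxon is new_taxon:
            return children[0]
        return GeneNode(node.id, node.event, new_taxon, node.species,
                        node.label, children, dict(node.extras))

    new_root = rebuild(family.root) if family.root is not None else None
    return ReconciledFamily(family.family_id, new_root, stree,
                            normalized=family.normalized)


# ---------------------------------------------------------------------------
# collapse-set maintenance helpers

def _add_collapsed(state: ViewState, family: ReconciledFamily, node: GeneNode) -> None:
    """Add ``node`` to the collapsed set, dropping collapsed descendants so the
    set stays an antichain of topmost nodes."""
    cache = state.cache(family)
    collapsed = state.collapsed_genes[family.family_id]
    sub_ids = {n.id for n in node.walk()}
    collapsed.difference_update(sub_ids - {node.id})
    collapsed.add(node.id)


def _is_displayed(state: ViewState, family: ReconciledFamily, node: GeneNode) -> bool:
    """True if no strict ancestor of ``node`` is collapsed."""
    cache = state.cache(family)
    collapsed = state.collapsed_genes[family.family_id]
    return not any(anc.id in collapsed for anc in cache.ancestors(node.id))


def _taxon_displayed(state: ViewState, taxon: SpeciesNode) -> bool:
    if not state.species_tree.is_ancestor_or_self(state.display_root, taxon):
        return False
    node = taxon.parent
    while node is not None:
        if node.id in state.collapsed_taxa:
            return False
        if node is state.display_root:
            break
        node = node.parent
    return True


def _enforce_cascade(state: ViewState) -> None:
    """Collapse the topmost displayed gene nodes lying inside collapsed taxa."""
    if not state.collapsed_taxa:
        return
    stree = state.species_tree
    hidden = [stree.index[tid] for tid in state.collapsed_taxa]

    def inside(taxon: SpeciesNode) -> bool:
        return any(stree.is_ancestor_or_self(h, taxon) for h in hidden)

    for family in state.families:
        collapsed = state.collapsed_genes[family.family_id]

        def visit(node: GeneNode) -> None:
            if node.id in collapsed:
                return
            if node.taxon is not None and inside(node.taxon):
                _add_collapsed(state, family, node)
                return
            for child in node.children:
                visit(child)

        visit(family.root)


# ---------------------------------------------------------------------------
# named collapse behaviors

def smart_collapse(state: ViewState) -> ViewState:
    """Collapse every maximal duplication-free subtree in every family."""
    for family in state.families:
        cache = state.cache(family)
        collapsed: set[str] = set()

        def visit(node: GeneNode) -> None:
            if not cache.has_dup[node.id]:
                collapsed.add(node.id)
                return
            for child in node.children:
                visit(child)

        visit(family.root)
        state.collapsed_genes[family.family_id] = collapsed
    _enforce_cascade(state)
    return state


def collapse_all(state: ViewState) -> ViewState:
    """Collapse every family to its root: one profile row per family."""
    for family in state.families:
        state.collapsed_genes[family.family_id] = {family.root.id}
    _enforce_cascade(state)
    return state


def expand_node(state: ViewState, family: ReconciledFamily, node: GeneNode) -> ViewState:
    """Reveal topology below ``node`` until the next duplication nodes.

    The newly collapsed set inside the subtree is the set of topmost strict
    descendants that are either duplications or duplication-free subtrees;
    speciation chains are revealed only where they lead to a duplication.
    """
    collapsed = state.collapsed_genes[family.family_id]
    if node.id not in collapsed:
        warnings.warn(f"node {node.id!r} is not collapsed; expand is a no-op",
                      stacklevel=2)
        return state
    if node.event in (LEAF, LOSS):
        return state
    cache = state.cache(family)
    collapsed.discard(node.id)

    def mark(d: GeneNode) -> None:
        if d.event == DUPLICATION or not cache.has_dup[d.id]:
            collapsed.add(d.id)
            return
        for child in d.children:
            mark(child)

    for child in node.children:
        mark(child)
    _enforce_cascade(state)
    return state


def collapse_node(state: ViewState, family: ReconciledFamily, node: GeneNode) -> ViewState:
    """Collapse a displayed node into a single profile row."""
    collapsed = state.collapsed_genes[family.family_id]
    if node.id in collapsed:
        return state
    if not _is_displayed(state, family, node):
        raise TreeMatrixError(
            f"node {node.id!r} is already hidden under a collapsed node")
    _add_collapsed(state, family, node)
    return state


def collapse_taxon(state: ViewState, taxon: SpeciesNode) -> ViewState:
    """Collapse a species-tree clade; cascades to the gene trees.

    The clade's column replaces its descendants' columns and, in every family,
    each topmost displayed gene node within the clade is collapsed -- so no
    gene-tree structure below the taxon remains visible, while expanding the
    taxon later can restore the previous state.
    """
    if taxon.id in state.collapsed_taxa:
        return state
    if taxon.is_leaf:
        raise TreeMatrixError(f"taxon {taxon.name!r} is an extant species; "
                              "nothing to collapse")
    if not _taxon_displayed(state, taxon):
        raise TreeMatrixError(f"taxon {taxon.name!r} is not displayed in this view")
    stree = state.species_tree
    for existing in list(state.collapsed_taxa):
        if stree.is_ancestor_or_self(taxon, stree.index[existing]):
            state.collapsed_taxa.discard(existing)
    state.collapsed_taxa.add(taxon.id)
    _enforce_cascade(state)
    return state


def auto_collapse_depth(state: ViewState, d: int) -> ViewState:
    """Collapse every internal species node at depth exactly ``d`` from the
    display root (root depth 0); deeper structure is thereby hidden."""
    if d < 0:
        raise TreeMatrixError("depth must be >= 0")
    root = state.display_root
    targets: list[SpeciesNode] = []

    def visit(node: SpeciesNode, depth: int) -> None:
        if depth == d:
            if not node.is_leaf:
                targets.append(node)
            return
        for child in node.children:
            visit(child, depth + 1)

    visit(root, 0)
    for taxon in targets:
        if taxon.id not in state.collapsed_taxa and _taxon_displayed(state, taxon):
            collapse_taxon(state, taxon)
    state.depth_limit = d
    return state


# ---------------------------------------------------------------------------
# what the view shows

def visible_columns(state: ViewState) -> list[SpeciesNode]:
    """Tips of the species tree after root restriction and taxon collapse,
    in species-tree left-to-right order.  One entry per profile column."""
    out: list[SpeciesNode] = []

    def visit(node: SpeciesNode) -> None:
        if node.id in state.collapsed_taxa or node.is_leaf:
            out.append(node)
            return
        for child in node.children:
            visit(child)

    visit(state.display_root)
    return out


def visible_tips(state: ViewState, family: ReconciledFamily) -> list[GeneNode]:
    """Displayed gene-tree tips (collapsed subfamilies, extant leaves, loss
    tips) in drawing order: children ordered by species-tree position of their
    taxon, duplication co-children tie-broken by descending extant-leaf count,
    then id.  One entry per matrix row."""
    cache = state.cache(family)
    collapsed = state.collapsed_genes[family.family_id]
    stree = state.species_tree
    out: list[GeneNode] = []

    def key(node: GeneNode):
        pos = stree.preorder_index(node.taxon) if node.taxon is not None else -1
        return (pos, -cache.n_leaves[node.id], node.id)

    def visit(node: GeneNode) -> None:
        if node.id in collapsed or node.is_tip:
            out.append(node)
            return
        for child in sorted(node.children, key=key):
            visit(child)

    visit(family.root)
    return out


def displayed_internal_nodes(state: ViewState, family: ReconciledFamily) -> list[GeneNode]:
    """Internal gene nodes currently drawn expanded (for layout/testing)."""
    collapsed = state.collapsed_genes[family.family_id]
    out: list[GeneNode] = []

    def visit(node: GeneNode) -> None:
        if node.id in collapsed or node.is_tip:
            return
        out.append(node)
        for child in node.children:
            visit(child)

    visit(family.root)
    return out
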