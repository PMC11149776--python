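"""Normalization of a reconciled family against its species tree.

Normalization makes the reconciliation fully explicit:

* ``insert_implied_speciations`` adds the speciation nodes that a gene-tree
  edge silently skips, so that every speciation's children map one-to-one
  onto children of its taxon, and every duplication child starts at the
  duplication's own taxon;
* ``infer_losses`` attaches one loss tip per species-tree child that a
  speciation leaves unrepresented -- the losses "implied from the species
  tree";
* ``leaf_counts`` is the brute-force per-species copy-number oracle that the
  profile computation is tested against;
* ``duplication_skeleton`` contracts the gene tree to its root and
  duplication nodes, the information-complete compact form of the family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import (
    DUPLICATION,
    LEAF,
    LOSS,
    SPECIATION,
    ConsistencyError,
    GeneNode,
    ReconciledFamily,
    SpeciesNode,
)


def insert_implied_speciations(family: ReconciledFamily) -> ReconciledFamily:
    """Insert the speciation chain on every edge that skips species-tree levels.

    For a speciation parent at taxon ``t`` with a child lineage at taxon ``u``
    strictly below a child ``c`` of ``t``, the chain covers ``c .. parent(u)``.
    For a duplication parent at ``t`` the chain starts at ``t`` itself, because
    a duplication child (a subfamily) originates where the duplication
    happened, and losses between that origin and the subfamily's extant span
    belong to the subfamily.  Inserted nodes carry explicit taxa and ids
    ``"<anchor_id>@<taxon_id>"`` where the anchor is the pre-existing child the
    chain leads to, so normalization is deterministic and round-trippable.
    """
    stree = family.species_tree

    def chain_taxa(parent: GeneNode, child: GeneNode) -> list[SpeciesNode]:
        t, u = parent.taxon, child.taxon
        if u is t:
            return []
        if not stree.is_ancestor_or_self(t, u):
            raise ConsistencyError(
                f"taxon {u.name!r} of {child.id!r} is disjoint from taxon "
                f"{t.name!r} of its parent {parent.id!r}")
        path = stree.path_down(t, u)  # t .. u inclusive
        if parent.event == DUPLICATION:
            return path[:-1]  # t .. parent(u)
        return path[1:-1]  # first step is explicit in the speciation itself

    def visit(node: GeneNode) -> None:
        if node.event in (LEAF, LOSS):
            return
        new_children: list[GeneNode] = []
        for child in node.children:
            if child.event == LOSS:
                new_children.append(child)
                continue
            taxa = chain_taxa(node, child)
            top = child
            for taxon in reversed(taxa):
                top = GeneNode(
                    id=f"{child.id}@{taxon.id}",
                    event=SPECIATION,
                    taxon=taxon,
                    label=taxon.name,
                    children=[top],
                    extras={"implied": True, "implied_for": child.id},
                )
            new_children.append(top)
            visit(child)
        node.children = new_children

    if family.root is not None:
        visit(family.root)
    return family


def infer_losses(family: ReconciledFamily) -> ReconciledFamily:
    """Attach loss tips for every species-tree child a speciation leaves empty.

    One loss tip is drawn per *maximal* lost clade: the tip's taxon is the
    species-tree child itself (which may be internal), labeled with its name.
    Children of every speciation are then ordered by species-tree position,
    which keeps serializations byte-stable.  Sets ``normalized``.
    """
    stree = family.species_tree

    def visit(node: GeneNode) -> None:
        for child in node.children:
            visit(child)
        if node.event != SPECIATION or node.taxon is None or node.taxon.is_leaf:
            return
        represented: set[str] = set()
        for child in node.children:
            if child.taxon is None:
                continue
            branch = child.taxon
            while branch is not None and branch.parent is not node.taxon:
                branch = branch.parent
            if branch is not None:
                represented.add(branch.id)
        for branch in node.taxon.children:
            if branch.id not in represented:
                node.children.append(GeneNode(
                    id=f"{node.id}%loss%{branch.id}",
                    event=LOSS,
                    taxon=branch,
                    label=branch.name,
                    extras={"implied": True},
                ))
        node.children.sort(key=lambda c: stree.preorder_index(c.taxon)
                           if c.taxon is not None else -1)

    if family.root is not None:
        visit(family.root)
    family.normalized = True
    return family


def normalize(family: ReconciledFamily) -> ReconciledFamily:
    """``insert_implied_speciations`` then ``infer_losses``.  Idempotent."""
    insert_implied_speciations(family)
    return infer_losses(family)


def leaf_counts(node: GeneNode) -> Counter:
    """Per-species extant gene copy counts under ``node`` (brute force).

    Species with zero copies are absent from the map; a loss tip therefore
    yields an empty Counter.
    """
    counts: Counter = Counter()
    for leaf in node.extant_leaves():
        counts[leaf.species.name] += 1
    return counts


@dataclass
class SkeletonNode:
    """Node of the duplication skeleton (a contracted gene tree)."""

    gene_node: GeneNode
    children: list["SkeletonNode"] = field(default_factory=list)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


def duplication_skeleton(family: ReconciledFamily) -> SkeletonNode:
    """Contract the gene tree to {root} U {duplication nodes}.

    Parent-child in the skeleton means nearest-duplication-ancestor in the
    gene tree.  Together with the species tree this is information-equivalent
    to the full (normalized) gene tree.
    """

    def collect_dups(node: GeneNode, out: list[SkeletonNode]) -> None:
        for child in node.children:
            if child.event == DUPLICATION:
                sk = SkeletonNode(child)
                out.append(sk)
                collect_dups(child, sk.children)
            else:
                collect_dups(child, out)

    root_sk = SkeletonNode(family.root)
    collect_dups(family.root, root_sk.children)
    return root_sk
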