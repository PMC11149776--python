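"""Shared fixtures: the toy species tree S = ((A,B)AB,C)R and two families.

F1 has no duplication: a single-copy family over all three species.
F2 has a root duplication at R with subfamily X (one gene in each of A, B, C)
and subfamily Y (a single extant gene a2 in species A).
"""

import pytest

from treematrix.io import read_species_newick
from treematrix.model import (
    GeneNode,
    ReconciledFamily,
    annotate_taxa,
    infer_events,
)
from treematrix.reconcile import normalize


@pytest.fixture
def stree():
    return read_species_newick("((A,B)AB,C)R;")


def make_leaf(stree, node_id, species):
    return GeneNode(node_id, "leaf", species=stree.resolve(species))


def build_f1(stree, normalized=True):
    root = GeneNode("F1root", children=[
        GeneNode("f1ab", children=[make_leaf(stree, "a1", "A"),
                                   make_leaf(stree, "b1", "B")]),
        make_leaf(stree, "c1", "C"),
    ])
    family = ReconciledFamily("F1", root, stree)
    annotate_taxa(family)
    infer_events(family)
    if normalized:
        normalize(family)
    return family


def build_f2(stree, normalized=True):
    x = GeneNode("X", label="X", children=[
        GeneNode("xab", children=[make_leaf(stree, "xa1", "A"),
                                  make_leaf(stree, "xb1", "B")]),
        make_leaf(stree, "xc1", "C"),
    ])
    root = GeneNode("F2root", children=[x, make_leaf(stree, "a2", "A")])
    family = ReconciledFamily("F2", root, stree)
    annotate_taxa(family)
    infer_events(family)
    if normalized:
        normalize(family)
    return family


@pytest.fixture
def f1(stree):
    return build_f1(stree)


@pytest.fixture
def f2(stree):
    return build_f2(stree)


@pytest.fixture
def f1_raw(stree):
    return build_f1(stree, normalized=False)


@pytest.fixture
def f2_raw(stree):
    return build_f2(stree, normalized=False)


def gene_trees_equal(a: GeneNode, b: GeneNode) -> bool:
    """Isomorphism with labels: same ids, events, taxa, species, child order."""
    if (a.id, a.event, a.label) != (b.id, b.event, b.label):
        return False
    if (a.taxon.name if a.taxon else None) != (b.taxon.name if b.taxon else None):
        return False
    if (a.species.name if a.species else None) != (b.species.name if b.species else None):
        return False
    if len(a.children) != len(b.children):
        return False
    return all(gene_trees_equal(x, y) for x, y in zip(a.children, b.children))
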