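"""Domain model: species trees, reconciled gene trees and their consistency contract.

A *reconciled* gene family is a rooted gene tree whose nodes are mapped onto a
rooted (possibly multifurcating) species tree.  Each gene node carries an
event label -- ``leaf``, ``speciation``, ``duplication`` or ``loss`` -- and a
*taxon*: the species-tree node where the gene lineage resided.  The central
contract is that speciations in the gene tree follow the same order as in the
species tree, which is what makes a single species tree usable as the shared
"column axis" for any number of families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

LEAF = "leaf"
SPECIATION = "speciation"
DUPLICATION = "duplication"
LOSS = "loss"

EVENTS = frozenset({LEAF, SPECIATION, DUPLICATION, LOSS})

#: Accepted spellings on input.  "transfer" is preserved for round-trips but
#: laid out as a speciation (no dedicated display semantics).
EVENT_SYNONYMS = {
    "leaf": LEAF,
    "gene": LEAF,
    "generef": LEAF,
    "extant": LEAF,
    "speciation": SPECIATION,
    "spec": SPECIATION,
    "orthologgroup": SPECIATION,
    "ortholog_group": SPECIATION,
    "duplication": DUPLICATION,
    "dup": DUPLICATION,
    "paraloggroup": DUPLICATION,
    "paralog_group": DUPLICATION,
    "loss": LOSS,
    "lost": LOSS,
    "transfer": SPECIATION,
    "horiz_transfer": SPECIATION,
}


class TreeMatrixError(Exception):
    """Base class for all model errors."""


class ResolutionError(TreeMatrixError):
    """A species or taxon name did not resolve against the species tree."""


class ConsistencyError(TreeMatrixError):
    """Gene tree and species tree disagree in a way that cannot be repaired."""


def normalize_event(raw: str) -> str:
    try:
        return EVENT_SYNONYMS[raw.strip().lower()]
    except KeyError:
        raise TreeMatrixError(f"unknown event label {raw!r}") from None


class SpeciesNode:
    """One node of the species tree (taxon).  Leaves are extant species."""

    __slots__ = ("id", "name", "children", "parent", "depth", "edge_length")

    def __init__(self, name: str, children: Optional[list["SpeciesNode"]] = None,
                 edge_length: float = 1.0) -> None:
        self.id = name
        self.name = name
        self.children: list[SpeciesNode] = list(children or [])
        self.parent: Optional[SpeciesNode] = None
        self.depth = 0
        self.edge_length = edge_length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesNode({self.name!r})"


class SpeciesTree:
    """Rooted taxonomy.  Leaf order (left to right) defines profile column order."""

    def __init__(self, root: SpeciesNode) -> None:
        self.root = root
        self.index: dict[str, SpeciesNode] = {}
        self.leaves: list[SpeciesNode] = []
        self._preorder: list[SpeciesNode] = []
        self._leafsets: dict[str, frozenset[str]] = {}
        self._wire()

    def _wire(self) -> None:
        self.index.clear()
        self.leaves.clear()
        self._preorder.clear()
        stack = [(self.root, None, 0)]
        order: list[SpeciesNode] = []
        while stack:
            node, parent, depth = stack.pop()
            node.parent = parent
            node.depth = depth
            order.append(node)
            for child in reversed(node.children):
                stack.append((child, node, depth + 1))
        for node in order:
            if node.name in self.index:
                raise TreeMatrixError(f"duplicate node name {node.name!r} in species tree")
            self.index[node.name] = node
            self._preorder.append(node)
            if node.is_leaf:
                self.leaves.append(node)
        self._order = {n.id: i for i, n in enumerate(self._preorder)}
        for node in reversed(self._preorder):
            if node.is_leaf:
                self._leafsets[node.id] = frozenset({node.name})
            else:
                self._leafsets[node.id] = frozenset(
                    itertools.chain.from_iterable(self._leafsets[c.id] for c in node.children)
                )

    def preorder(self) -> Iterator[SpeciesNode]:
        return iter(self._preorder)

    def preorder_index(self, node: SpeciesNode) -> int:
        return self._order[node.id]

    def leaf_set(self, node: SpeciesNode) -> frozenset[str]:
        """Names of extant species under (and including) ``node``."""
        return self._leafsets[node.id]

    def resolve(self, name: str) -> SpeciesNode:
        try:
            return self.index[name]
        except KeyError:
            raise ResolutionError(f"unknown taxon or species name {name!r}") from None

    def is_ancestor_or_self(self, anc: SpeciesNode, node: SpeciesNode) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def path_down(self, top: SpeciesNode, bottom: SpeciesNode) -> list[SpeciesNode]:
        """Nodes from ``top`` to ``bottom`` inclusive; error if not on one path."""
        rev = []
        node = bottom
        while node is not None and node is not top:
            rev.append(node)
            node = node.parent
        if node is None:
            raise ConsistencyError(
                f"{top.name!r} is not an ancestor of {bottom.name!r}")
        rev.append(top)
        return list(reversed(rev))

    def lca(self, nodes: Iterable[SpeciesNode]) -> SpeciesNode:
        nodes = list(nodes)
        if not nodes:
            raise TreeMatrixError("LCA of an empty node set is undefined")
        current = nodes[0]
        for other in nodes[1:]:
            a, b = current, other
            while a.depth > b.depth:
                a = a.parent
            while b.depth > a.depth:
                b = b.parent
            while a is not b:
                a, b = a.parent, b.parent
            current = a
        return current


def auto_name_internals(root: SpeciesNode, taken: Optional[set[str]] = None) -> None:
    """Give unnamed internal nodes deterministic names from the sorted pair of
    their extreme (leftmost / rightmost) leaf names, so ids are stable across
    runs and across tree rotations."""
    if taken is None:
        taken = set()
        def collect(n: SpeciesNode) -> None:
            if n.name:
                taken.add(n.name)
            for c in n.children:
                collect(c)
        collect(root)

    def extremes(n: SpeciesNode) -> tuple[str, str]:
        while n.children:
            n_first = n.children[0]
            n = n_first
        first = n.name
        return first, first

    def leftmost(n: SpeciesNode) -> SpeciesNode:
        while n.children:
            n = n.children[0]
        return n

    def rightmost(n: SpeciesNode) -> SpeciesNode:
        while n.children:
            n = n.children[-1]
        return n

    def visit(n: SpeciesNode) -> None:
        for c in n.children:
            visit(c)
        if not n.is_leaf and not n.name:
            a, b = sorted((leftmost(n).name, rightmost(n).name))
            name = f"{a}_{b}"
            while name in taken:
                name += "_"
            n.name = name
            n.id = name
            taken.add(name)

    visit(root)


class GeneNode:
    """One node of a reconciled gene tree."""

    __slots__ = ("id", "event", "taxon", "species", "label", "children", "extras")

    def __init__(self, id: str, event: Optional[str] = None,
                 taxon: Optional[SpeciesNode] = None,
                 species: Optional[SpeciesNode] = None,
                 label: Optional[str] = None,
                 children: Optional[list["GeneNode"]] = None,
                 extras: Optional[dict] = None) -> None:
        self.id = id
        self.event = event
        self.taxon = taxon
        self.species = species
        self.label = label
        self.children: list[GeneNode] = list(children or [])
        self.extras: dict = dict(extras or {})

    @property
    def is_tip(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["GeneNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def extant_leaves(self) -> Iterator["GeneNode"]:
        for node in self.walk():
            if node.event == LEAF:
                yield node

    def extant_species_names(self) -> frozenset[str]:
        return frozenset(leaf.species.name for leaf in self.extant_leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tax = self.taxon.name if self.taxon else None
        return f"GeneNode({self.id!r}, {self.event!r}, taxon={tax!r})"


class ReconciledFamily:
    """A gene tree reconciled with ``species_tree``.

    ``normalized`` is True once implied speciations and loss tips have been
    inserted (see :mod:`treematrix.reconcile`).
    """

    def __init__(self, family_id: str, root: GeneNode,
                 species_tree: SpeciesTree, normalized: bool = False) -> None:
        self.family_id = family_id
        self.root = root
        self.species_tree = species_tree
        self.normalized = normalized

    def nodes(self) -> Iterator[GeneNode]:
        return self.root.walk()

    def node_index(self) -> dict[str, GeneNode]:
        idx: dict[str, GeneNode] = {}
        for node in self.nodes():
            if node.id in idx:
                raise TreeMatrixError(
                    f"duplicate gene node id {node.id!r} in family {self.family_id!r}")
            idx[node.id] = node
        return idx

    def parents(self) -> dict[str, GeneNode]:
        par: dict[str, GeneNode] = {}
        for node in self.nodes():
            for child in node.children:
                par[child.id] = node
        return par


@dataclass
class Violation:
    gene_node_id: str
    rule_code: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, node_id: str, code: str, message: str) -> None:
        self.violations.append(Violation(node_id, code, message))


def annotate_taxa(family: ReconciledFamily,
                  stree: Optional[SpeciesTree] = None) -> ReconciledFamily:
    """Assign every gene node its taxon: the LCA of its extant descendants.

    Explicit taxon annotations (including those of loss tips and of implied
    speciations) are kept.  Idempotent.
    """
    stree = stree or family.species_tree
    if family.root is None:
        raise TreeMatrixError("empty family cannot be annotated")

    def visit(node: GeneNode) -> None:
        for child in node.children:
            visit(child)
        if node.event == LEAF or (node.is_tip and node.event not in (LOSS,)):
            if node.species is None:
                raise ResolutionError(
                    f"extant leaf {node.id!r} has no species assignment")
            node.event = LEAF
            node.taxon = node.species
            return
        if node.taxon is not None:
            return
        if node.event == LOSS:
            raise TreeMatrixError(
                f"loss node {node.id!r} must carry an explicit taxon")
        spans = [c.taxon for c in node.children
                 if c.taxon is not None and c.event != LOSS and _has_extant(c)]
        if not spans:
            raise TreeMatrixError(
                f"node {node.id!r} has no extant descendants and no explicit taxon")
        node.taxon = stree.lca(spans)

    visit(family.root)
    return family


def _has_extant(node: GeneNode) -> bool:
    return any(True for _ in node.extant_leaves())


def infer_events(family: ReconciledFamily) -> ReconciledFamily:
    """Label unlabeled internal nodes by species overlap.

    A node is a duplication iff the extant-species sets of at least two of its
    children intersect; otherwise it is a speciation.  Existing labels are
    preserved, so inputs that arrive labeled (e.g. from orthoXML) pass through
    unchanged.
    """
    spans: dict[str, frozenset[str]] = {}

    def visit(node: GeneNode) -> None:
        for child in node.children:
            visit(child)
        if node.event == LEAF or node.is_tip and node.event != LOSS:
            spans[node.id] = frozenset({node.species.name})
            return
        if node.event == LOSS:
            spans[node.id] = frozenset()
            return
        spans[node.id] = frozenset(
            itertools.chain.from_iterable(spans[c.id] for c in node.children))
        if node.event is None:
            child_spans = [spans[c.id] for c in node.children]
            overlap = any(a & b for a, b in itertools.combinations(child_spans, 2))
            node.event = DUPLICATION if overlap else SPECIATION

    visit(family.root)
    return family


def validate_reconciliation(family: ReconciledFamily,
                            stree: Optional[SpeciesTree] = None) -> ValidationReport:
    """Check the gene-tree/species-tree consistency contract.

    All problems become report entries (never exceptions), one per offending
    node with a stable rule code.
    """
    stree = stree or family.species_tree
    report = ValidationReport()
    seen_ids: set[str] = set()

    def visit(node: GeneNode) -> None:
        if node.id in seen_ids:
            report.add(node.id, "duplicate-id", "gene node id appears twice")
        seen_ids.add(node.id)
        if node.event not in EVENTS:
            report.add(node.id, "bad-event", f"unknown event {node.event!r}")
        if node.taxon is None:
            report.add(node.id, "missing-taxon", "node has no taxon assignment")
        elif stree.index.get(node.taxon.name) is not node.taxon:
            report.add(node.id, "foreign-taxon",
                       f"taxon {node.taxon.name!r} is not a node of the species tree")
        if node.event == LEAF:
            if node.children:
                report.add(node.id, "leaf-children", "extant leaf has children")
            if node.species is None or node.taxon is not node.species or not node.species.is_leaf:
                report.add(node.id, "leaf-taxon",
                           "leaf taxon must equal its (extant) species")
        elif node.event == LOSS:
            if node.children:
                report.add(node.id, "loss-children", "loss tip has children")
        else:
            if not node.children:
                report.add(node.id, "childless-internal",
                           f"{node.event} node has no children")
        for child in node.children:
            if node.taxon is not None and child.taxon is not None \
                    and stree.index.get(node.taxon.name) is node.taxon \
                    and stree.index.get(child.taxon.name) is child.taxon:
                if not stree.is_ancestor_or_self(node.taxon, child.taxon):
                    report.add(child.id, "child-taxon-above-parent",
                               f"child taxon {child.taxon.name!r} is not at or below "
                               f"parent taxon {node.taxon.name!r}")
            visit(child)
        if node.event == SPECIATION and node.taxon is not None and node.children:
            _check_speciation(node)
        if family.normalized and node.event == DUPLICATION and node.taxon is not None:
            if len(node.children) < 2:
                report.add(node.id, "dup-arity",
                           "normalized duplication must have >= 2 children")
            for child in node.children:
                if child.taxon is not node.taxon:
                    report.add(child.id, "dup-child-taxon",
                               "normalized duplication child must sit at the "
                               "duplication's taxon")

    def _check_speciation(node: GeneNode) -> None:
        t = node.taxon
        mapped: dict[str, list[str]] = {}
        for child in node.children:
            if child.taxon is None or stree.index.get(child.taxon.name) is not child.taxon:
                continue
            if child.taxon is t:
                report.add(child.id, "speciation-child-same-taxon",
                           f"child of speciation at {t.name!r} sits at the same taxon")
                continue
            if not stree.is_ancestor_or_self(t, child.taxon):
                continue  # reported as child-taxon-above-parent already
            branch = child.taxon
            while branch.parent is not t:
                branch = branch.parent
            mapped.setdefault(branch.id, []).append(child.id)
            if family.normalized and child.taxon is not branch:
                report.add(child.id, "speciation-skipped-level",
                           f"normalized speciation child at {child.taxon.name!r} "
                           f"skips levels below {t.name!r}")
        for branch_id, ids in mapped.items():
            if len(ids) > 1:
                for cid in ids[1:]:
                    report.add(cid, "speciation-children-overlap",
                               "sibling lineages map to the same species child "
                               "under a speciation")
        if family.normalized:
            for branch in t.children:
                if branch.id not in mapped:
                    report.add(node.id, "speciation-missing-loss",
                               f"child {branch.name!r} of taxon {t.name!r} is neither "
                               "represented nor marked lost")

    visit(family.root)
    return report
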