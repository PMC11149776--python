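"""Synthetic gene families: a birth-death process along a species tree.

One ancestral gene enters the species-tree root.  Along every species-tree
edge each gene lineage independently experiences duplications (rate ``lam``)
and losses (rate ``mu``) as a continuous-time process per unit branch length;
at every speciation all surviving lineages enter every child edge.  The
returned family is the *observable* one: extinct lineages are pruned, unary
internals (speciations or duplications with a single surviving child) are
contracted, and taxa re-annotated by LCA of survivors -- exactly what a real
reconciled gene tree shows.

Ground truth shipped with each family:

* ``event_log`` -- every duplication/loss drawn, with the species-tree edge
  and lineage it happened on;
* ``true_duplications`` / ``observable_duplications`` -- all surviving
  duplication node ids vs. those whose surviving child spans overlap (the
  ones species-overlap labeling can detect);
* ``observable_losses`` -- per subfamily, the maximal species clades with
  zero surviving members inside the subfamily's span, computed by direct
  species-tree recursion (independently of the normalization code it is used
  to test).

With the default fixed per-edge branch length the expected per-species copy
number has the closed form ``exp((lam - mu) * depth(s) * branch_length)``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    DUPLICATION,
    LEAF,
    SPECIATION,
    GeneNode,
    ReconciledFamily,
    SpeciesNode,
    SpeciesTree,
    annotate_taxa,
    auto_name_internals,
)


@dataclass(frozen=True)
class SimConfig:
    dup_rate: float = 0.1        # lam, duplications per lineage per unit length
    loss_rate: float = 0.05      # mu, losses per lineage per unit length
    seed: int = 0
    branch_length: float = 1.0   # fixed length of every species-tree edge

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0 or self.branch_length <= 0:
            raise ValueError("rates must be >= 0 and branch length > 0")


@dataclass
class SimulatedFamily:
    family: Optional[ReconciledFamily]      # None if the family went extinct
    event_log: list[tuple[str, str, str]]   # (event, species edge, lineage id)
    true_duplications: set[str]
    observable_duplications: set[str]
    observable_losses: dict[str, list[str]]  # subfamily root id -> lost clade ids
    config: SimConfig = field(default=None)  # type: ignore[assignment]

    @property
    def extinct(self) -> bool:
        return self.family is None


def simulate_species_tree(n_species: int, seed: int) -> SpeciesTree:
    """Pure-birth (Yule) topology with ``n_species`` leaves named S1..Sn in
    left-to-right order; deterministic per seed."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = random.Random(seed)
    root = SpeciesNode("")
    root.children = [SpeciesNode(""), SpeciesNode("")]
    leaves = list(root.children)
    while len(leaves) < n_species:
        pick = rng.randrange(len(leaves))
        node = leaves.pop(pick)
        node.children = [SpeciesNode(""), SpeciesNode("")]
        leaves.extend(node.children)

    counter = [0]

    def name_leaves(node: SpeciesNode) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"S{counter[0]}"
            node.id = node.name
            return
        for child in node.children:
            name_leaves(child)

    name_leaves(root)
    auto_name_internals(root)

    def reset_ids(node: SpeciesNode) -> None:
        node.id = node.name
        for child in node.children:
            reset_ids(child)

    reset_ids(root)
    return SpeciesTree(root)


def simulate_family(stree: SpeciesTree, cfg: SimConfig,
                    family_id: str = "sim") -> SimulatedFamily:
    """Run the birth-death process and return the observable family with its
    ground-truth event log."""
    rng = random.Random(cfg.seed)
    lam, mu = cfg.dup_rate, cfg.loss_rate
    total = lam + mu
    log: list[tuple[str, str, str]] = []
    true_dups: set[str] = set()
    lineage_counter = [0]

    def new_id(prefix: str) -> str:
        lineage_counter[0] += 1
        return f"{prefix}{lineage_counter[0]}"

    def at_node(sp: SpeciesNode, lineage: str) -> Optional[GeneNode]:
        """A lineage that reached species node ``sp`` alive."""
        if sp.is_leaf:
            return GeneNode(new_id("g"), LEAF, taxon=sp, species=sp,
                            label=f"{sp.name}|{lineage}")
        node_id = new_id("s")
        children = []
        for child_sp in sp.children:
            sub = along_edge(child_sp, cfg.branch_length, lineage)
            if sub is not None:
                children.append(sub)
        if not children:
            return None
        if len(children) == 1:
            return children[0]  # unobservable speciation; losses are implied
        return GeneNode(node_id, SPECIATION, children=children)

    def along_edge(sp: SpeciesNode, remaining: float,
                   lineage: str) -> Optional[GeneNode]:
        """One lineage travelling down the edge into ``sp``."""
        while True:
            if total == 0:
                return at_node(sp, lineage)
            wait = rng.expovariate(total)
            if wait >= remaining:
                return at_node(sp, lineage)
            remaining -= wait
            if rng.random() < mu / total:
                log.append(("loss", sp.id, lineage))
                return None
            dup_id = new_id("d")
            log.append(("duplication", sp.id, dup_id))
            left = along_edge(sp, remaining, new_id("l"))
            right = along_edge(sp, remaining, new_id("l"))
            survivors = [x for x in (left, right) if x is not None]
            if not survivors:
                return None
            if len(survivors) == 1:
                return survivors[0]  # unobservable duplication
            true_dups.add(dup_id)
            return GeneNode(dup_id, DUPLICATION, children=survivors)

    root_lineage = new_id("l")
    root = at_node(stree.root, root_lineage)
    if root is None:
        return SimulatedFamily(None, log, set(), set(), {}, cfg)
    family = ReconciledFamily(family_id, root, stree)
    annotate_taxa(family)
    obs_dups = _observable_duplications(family)
    losses = _observable_losses(family, stree)
    return SimulatedFamily(family, log, true_dups, obs_dups, losses, cfg)


def _observable_duplications(family: ReconciledFamily) -> set[str]:
    """Surviving duplications whose surviving child spans overlap -- the set
    species-overlap labeling can recover."""
    out: set[str] = set()
    for node in family.nodes():
        if node.event != DUPLICATION:
            continue
        spans = [c.extant_species_names() for c in node.children]
        if any(a & b for i, a in enumerate(spans) for b in spans[i + 1:]):
            out.add(node.id)
    return out


def _observable_losses(family: ReconciledFamily,
                       stree: SpeciesTree) -> dict[str, list[str]]:
    """Per-subfamily maximal lost clades, by species-tree recursion.

    Subfamilies are the family root plus every child lineage of a surviving
    duplication; a subfamily's origin is its duplication's taxon (the root's
    own taxon for the root).  Within the origin's span, a clade is a loss of
    this subfamily when it has no surviving member at all and does not lie
    strictly inside the span of a nested duplication (losses there belong to
    the nested subfamilies).
    """
    out: dict[str, list[str]] = {}

    def handoffs(node: GeneNode) -> list[SpeciesNode]:
        """Taxa of the nearest duplication descendants (incl. node itself)."""
        if node.event == DUPLICATION:
            return [node.taxon]
        found: list[SpeciesNode] = []
        for child in node.children:
            found.extend(handoffs(child))
        return found

    def lost_clades(origin: SpeciesNode, survivors: frozenset[str],
                    stops: set[str]) -> list[str]:
        lost: list[str] = []

        def visit(u: SpeciesNode) -> None:
            if u.id in stops:
                return
            if not (stree.leaf_set(u) & survivors):
                lost.append(u.id)
                return
            for child in u.children:
                visit(child)

        visit(origin)
        return lost

    def subfamily(root: GeneNode, origin: SpeciesNode) -> None:
        survivors = root.extant_species_names()
        stops = {t.id for t in handoffs(root)}
        out[root.id] = sorted(lost_clades(origin, survivors, stops))
        # nested subfamilies: the children of the nearest duplications
        def descend(node: GeneNode) -> None:
            if node.event == DUPLICATION:
                for child in node.children:
                    subfamily(child, node.taxon)
                return
            for child in node.children:
                descend(child)

        if root.event == DUPLICATION:
            for child in root.children:
                subfamily(child, root.taxon)
        else:
            for child in root.children:
                descend(child)

    subfamily(family.root, family.root.taxon)
    return out


def losses_from_normalized(family: ReconciledFamily) -> dict[str, list[str]]:
    """Group the loss tips of a *normalized* family by subfamily.

    Subfamily keys match :func:`_observable_losses`: the family root id and,
    for every duplication child, the id of the pre-normalization child node
    (implied chain tops resolve through their anchor).  Used to compare the
    normalization machinery against the simulator's ground truth.
    """
    from .model import LOSS  # local to avoid polluting module namespace

    out: dict[str, list[str]] = {}

    def start(node: GeneNode, key: str) -> None:
        acc: list[str] = []

        def walk(n: GeneNode) -> None:
            if n.event == LOSS:
                acc.append(n.taxon.id)
                return
            if n.event == DUPLICATION:
                for child in n.children:
                    start(child, child.extras.get("implied_for", child.id))
                return
            for child in n.children:
                walk(child)

        if node.event == DUPLICATION:
            out[key] = []
            for child in node.children:
                start(child, child.extras.get("implied_for", child.id))
        else:
            walk(node)
            out[key] = sorted(acc)

    start(family.root, family.root.id)
    return out


def expected_copy_number(stree: SpeciesTree, cfg: SimConfig,
                         species: SpeciesNode) -> float:
    """Closed-form expectation exp((lam - mu) * T) with T the root-to-leaf
    path length of ``species`` (edges x fixed branch length)."""
    return math.exp((cfg.dup_rate - cfg.loss_rate) * species.depth * cfg.branch_length)
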