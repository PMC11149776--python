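"""Readers and writers.

* species trees: newick (dendropy-backed), child order preserved, unnamed
  internal nodes auto-named deterministically;
* gene families: a documented JSON dialect (the tool's native format) with a
  canonical writer so round-trips are byte-stable;
* orthoXML (read-only): orthologGroup -> speciation, paralogGroup ->
  duplication, geneRef -> extant leaf;
* OMA / PANTHER family identifiers: fetched over HTTP with every raw response
  cached on disk, so repeated calls -- and the whole test suite -- are
  offline.

JSON dialect (one node object per gene-tree node)::

    {"id": "g1", "event": "leaf|speciation|duplication|loss|transfer",
     "taxon": "<species-tree node name>",   # optional; inferred by LCA
     "species": "<extant species name>",    # leaves only
     "label": "<display string>",           # optional
     "children": [ ... ]}                   # absent/empty for tips

The document may be a bare node or ``{"family_id": ..., "normalized": bool,
"root": <node>}``.  Unknown fields are preserved for round-trips.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from pathlib import Path
from typing import Optional

import dendropy
from lxml import etree

from .model import (
    LEAF,
    LOSS,
    ConsistencyError,
    GeneNode,
    ReconciledFamily,
    ResolutionError,
    SpeciesNode,
    SpeciesTree,
    TreeMatrixError,
    annotate_taxa,
    auto_name_internals,
    infer_events,
    normalize_event,
    validate_reconciliation,
)

_RESERVED = {"id", "event", "taxon", "species", "label", "children"}


# ---------------------------------------------------------------------------
# species trees

def read_species_newick(text: str) -> SpeciesTree:
    """Parse a newick species tree, preserving child order and branch lengths.

    Leaf names must be unique; unnamed internal nodes receive deterministic
    auto-names built from the sorted pair of their extreme leaf names.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeMatrixError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> SpeciesNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            if not name:
                raise TreeMatrixError("unnamed leaf in species tree")
            node = SpeciesNode(name)
        else:
            node = SpeciesNode(dnode.label or "")
            node.children = [convert(c) for c in dnode.child_nodes()]
        if dnode.edge is not None and dnode.edge.length is not None:
            node.edge_length = float(dnode.edge.length)
        return node

    root = convert(dtree.seed_node)
    leaf_names: list[str] = []

    def collect(n: SpeciesNode) -> None:
        if n.is_leaf:
            leaf_names.append(n.name)
        for c in n.children:
            collect(c)

    collect(root)
    dupes = {n for n in leaf_names if leaf_names.count(n) > 1}
    if dupes:
        raise TreeMatrixError(f"duplicate leaf names in species tree: {sorted(dupes)}")
    auto_name_internals(root)

    def reset_ids(n: SpeciesNode) -> None:
        n.id = n.name
        for c in n.children:
            reset_ids(c)

    reset_ids(root)
    return SpeciesTree(root)


def species_to_newick(stree: SpeciesTree) -> str:
    def render(node: SpeciesNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.edge_length:g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.name}:{node.edge_length:g}"
    return render(stree.root) + ";"


def induce_species_tree(stree: SpeciesTree, species_names: set[str]) -> SpeciesTree:
    """Restrict a taxonomy to a species subset (prune + contract unary nodes)."""
    missing = {s for s in species_names if s not in stree.index
               or not stree.index[s].is_leaf}
    if missing:
        raise ResolutionError(f"species not in the service taxonomy: {sorted(missing)}")

    def rebuild(node: SpeciesNode) -> Optional[SpeciesNode]:
        if node.is_leaf:
            if node.name not in species_names:
                return None
            copy = SpeciesNode(node.name, edge_length=node.edge_length)
            return copy
        children = [c2 for c in node.children if (c2 := rebuild(c)) is not None]
        if not children:
            return None
        if len(children) == 1:
            child = children[0]
            child.edge_length += node.edge_length
            return child
        copy = SpeciesNode(node.name, children, edge_length=node.edge_length)
        return copy

    root = rebuild(stree.root)
    if root is None:
        raise TreeMatrixError("no requested species found in the taxonomy")
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# native JSON dialect

def family_from_json(text: str, stree: SpeciesTree,
                     family_id: Optional[str] = None) -> ReconciledFamily:
    """Parse the native JSON dialect into a validated, taxon-annotated family."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TreeMatrixError(f"JSON parse error: {exc}") from exc
    if "root" in doc:
        root_doc = doc["root"]
        family_id = family_id or doc.get("family_id", "family")
        normalized = bool(doc.get("normalized", False))
    else:
        root_doc = doc
        family_id = family_id or "family"
        normalized = False
    seen_ids: set[str] = set()
    counter = [0]

    def build(obj: dict) -> GeneNode:
        if not isinstance(obj, dict):
            raise TreeMatrixError("gene-tree node must be a JSON object")
        counter[0] += 1
        node_id = str(obj.get("id", f"n{counter[0]}"))
        if node_id in seen_ids:
            raise TreeMatrixError(f"duplicate gene node id {node_id!r}")
        seen_ids.add(node_id)
        raw_event = obj.get("event")
        event = normalize_event(raw_event) if raw_event is not None else None
        extras = {k: v for k, v in obj.items() if k not in _RESERVED}
        if raw_event is not None and raw_event.strip().lower() in ("transfer", "horiz_transfer"):
            extras["original_event"] = raw_event.strip().lower()
        species = stree.resolve(obj["species"]) if obj.get("species") else None
        if species is not None and not species.is_leaf:
            raise ResolutionError(
                f"species {species.name!r} of node {node_id!r} is not extant")
        taxon = stree.resolve(obj["taxon"]) if obj.get("taxon") else None
        children = [build(c) for c in obj.get("children", [])]
        if not children and event is None and species is not None:
            event = LEAF
        return GeneNode(node_id, event, taxon, species, obj.get("label"),
                        children, extras)

    family = ReconciledFamily(family_id, build(root_doc), stree, normalized=normalized)
    annotate_taxa(family)
    infer_events(family)
    report = validate_reconciliation(family)
    if not report.ok:
        first = report.violations[0]
        raise ConsistencyError(
            f"family {family_id!r} is inconsistent with the species tree "
            f"({len(report.violations)} violations; first: node "
            f"{first.gene_node_id!r} {first.rule_code}: {first.message})")
    return family


def _node_to_obj(node: GeneNode) -> dict:
    obj: dict = dict(node.extras)
    obj.pop("original_event", None)
    obj["id"] = node.id
    obj["event"] = node.extras.get("original_event", node.event)
    if node.taxon is not None:
        obj["taxon"] = node.taxon.name
    if node.species is not None:
        obj["species"] = node.species.name
    if node.label is not None:
        obj["label"] = node.label
    if node.children:
        obj["children"] = [_node_to_obj(c) for c in node.children]
    return obj


def family_to_json(family: ReconciledFamily) -> str:
    """Canonical serialization: sorted keys, stable child order, 2-space
    indent.  ``family_from_json(family_to_json(f))`` is the identity on the
    model and the output is byte-identical across runs."""
    doc = {
        "family_id": family.family_id,
        "normalized": family.normalized,
        "root": _node_to_obj(family.root),
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------
# orthoXML

def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def family_from_orthoxml(xml_text: str | bytes, stree: SpeciesTree,
                         family_id: Optional[str] = None) -> ReconciledFamily:
    """Convert an orthoXML document (one top-level group) to a family.

    orthologGroup -> speciation, paralogGroup -> duplication, geneRef ->
    extant leaf whose species comes from the gene declarations.  Taxa are
    then annotated by LCA and the result validated.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise TreeMatrixError(f"orthoXML parse error: {exc}") from exc

    genes: dict[str, tuple[str, str]] = {}  # internal id -> (display id, species)
    for sp in root.iter():
        if _local(sp.tag) != "species":
            continue
        sp_name = sp.get("name") or sp.get("NCBITaxId") or ""
        for gene in sp.iter():
            if _local(gene.tag) != "gene":
                continue
            gid = gene.get("id")
            display = gene.get("protId") or gene.get("geneId") or gid
            if gid is not None:
                genes[gid] = (display, sp_name)

    groups = None
    for el in root.iter():
        if _local(el.tag) == "groups":
            groups = el
            break
    if groups is None:
        raise TreeMatrixError("orthoXML document has no <groups> section")
    top = [el for el in groups
           if _local(el.tag) in ("orthologGroup", "paralogGroup")]
    if not top:
        raise TreeMatrixError("orthoXML <groups> section is empty")

    counter = [0]

    def build(el) -> GeneNode:
        kind = _local(el.tag)
        if kind == "geneRef":
            gid = el.get("id")
            if gid not in genes:
                raise TreeMatrixError(f"geneRef to undeclared gene id {gid!r}")
            display, sp_name = genes[gid]
            species = stree.resolve(sp_name)
            if not species.is_leaf:
                raise ResolutionError(f"declared species {sp_name!r} is not extant")
            return GeneNode(display, LEAF, species=species, label=display)
        counter[0] += 1
        event = "speciation" if kind == "orthologGroup" else "duplication"
        node_id = el.get("id") or f"{kind[:1]}g{counter[0]}"
        taxon = None
        for child in el:
            if _local(child.tag) == "property" and \
                    child.get("name") in ("TaxRange", "TaxId", "taxon"):
                value = child.get("value")
                if value in stree.index:
                    taxon = stree.index[value]
        children = [build(c) for c in el
                    if _local(c.tag) in ("orthologGroup", "paralogGroup", "geneRef")]
        if not children:
            raise TreeMatrixError(f"empty group {node_id!r} in orthoXML")
        if len(children) == 1:
            return children[0]
        return GeneNode(node_id, event, taxon=taxon, children=children,
                        label=el.get("id"))

    if len(top) > 1:
        counter[0] += 1
        gene_root = GeneNode("og_root", "speciation",
                             children=[build(el) for el in top])
    else:
        gene_root = build(top[0])
    family = ReconciledFamily(family_id or root.get("origin", "orthoxml_family"),
                              gene_root, stree)
    annotate_taxa(family)
    infer_events(family)
    report = validate_reconciliation(family)
    if not report.ok:
        first = report.violations[0]
        raise ConsistencyError(
            f"orthoXML family is inconsistent with the species tree (first: "
            f"node {first.gene_node_id!r} {first.rule_code}: {first.message})")
    return family


# ---------------------------------------------------------------------------
# network adapters (OMA / PANTHER), isolated behind an on-disk cache

_ENDPOINTS = {
    "oma": {
        "family": "https://omabrowser.org/api/hog/{id}/orthoxml/",
        "species": "https://omabrowser.org/api/taxonomy/?type=newick",
        "ext": "orthoxml",
    },
    "panther": {
        "family": "https://www.pantherdb.org/services/oai/pantherdb/treeinfo?family={id}",
        "species": "https://data.pantherdb.org/ftp/species_tree/current_release/species_tree.nwk",
        "ext": "json",
    },
}


def _cached_get(url: str, cache_path: Path, identifier: str, timeout: float = 30.0) -> str:
    if cache_path.exists():
        return cache_path.read_text()
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            text = response.read().decode()
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise TreeMatrixError(
            f"cannot fetch {identifier!r} ({exc}) and no cached response at "
            f"{cache_path}") from exc
    cache_path.parent.mkdir(parents=True, exist_ok=True)
    cache_path.write_text(text)
    return text


def _service_species_tree(source: str, cache_dir: Path) -> SpeciesTree:
    spec = _ENDPOINTS[source]
    path = cache_dir / source / "species.nwk"
    text = _cached_get(spec["species"], path, f"{source} species tree")
    if text.lstrip().startswith("{"):  # some endpoints wrap newick in JSON
        text = json.loads(text).get("newick", "")
    return read_species_newick(text)


def _panther_family_from_json(text: str, stree: SpeciesTree,
                              family_id: str) -> ReconciledFamily:
    doc = json.loads(text)
    node = doc
    for key in ("search", "tree_topology", "annotation_node"):
        if isinstance(node, dict) and key in node:
            node = node[key]

    counter = [0]

    def build(obj: dict) -> GeneNode:
        counter[0] += 1
        kids = obj.get("children") or {}
        kid_nodes = kids.get("annotation_node", []) if isinstance(kids, dict) else kids
        if isinstance(kid_nodes, dict):
            kid_nodes = [kid_nodes]
        node_id = str(obj.get("accession") or obj.get("persistent_id")
                      or f"an{counter[0]}")
        label = obj.get("gene_symbol") or obj.get("node_name")
        if not kid_nodes:
            sp_name = obj.get("organism") or obj.get("species") or obj.get("taxon")
            if sp_name is None:
                raise TreeMatrixError(f"leaf node {node_id!r} has no species")
            return GeneNode(node_id, LEAF, species=stree.resolve(str(sp_name)),
                            label=label or node_id)
        raw = (obj.get("event_type") or "speciation")
        event = normalize_event(str(raw))
        taxon = None
        trange = obj.get("taxonomic_range")
        if trange in stree.index:
            taxon = stree.index[trange]
        return GeneNode(node_id, event, taxon=taxon, label=label,
                        children=[build(k) for k in kid_nodes])

    family = ReconciledFamily(family_id, build(node), stree)
    annotate_taxa(family)
    infer_events(family)
    return family


def fetch_families(source: str, family_ids: list[str],
                   cache_dir: str | Path) -> tuple[list[ReconciledFamily], SpeciesTree]:
    """Fetch one or more families by identifier from OMA or PANTHER.

    Raw responses are cached under ``cache_dir/<source>/``; with a warm cache
    no network access happens.  All families are rebuilt over one species
    tree: the service taxonomy induced on the union of their species.
    """
    if source not in _ENDPOINTS:
        raise TreeMatrixError(f"unknown source {source!r}; expected 'oma' or 'panther'")
    if not family_ids or any(not fid for fid in family_ids):
        raise TreeMatrixError("family identifiers must be non-empty")
    cache_dir = Path(cache_dir)
    spec = _ENDPOINTS[source]
    service_tree = _service_species_tree(source, cache_dir)
    raw: dict[str, str] = {}
    for fid in family_ids:
        path = cache_dir / source / f"{fid}.{spec['ext']}"
        raw[fid] = _cached_get(spec["family"].format(id=fid), path, fid)

    def parse(fid: str, stree: SpeciesTree) -> ReconciledFamily:
        if source == "oma":
            return family_from_orthoxml(raw[fid], stree, family_id=fid)
        return _panther_family_from_json(raw[fid], stree, family_id=fid)

    all_species: set[str] = set()
    for fid in family_ids:
        probe = parse(fid, service_tree)
        all_species |= {leaf.species.name for leaf in probe.root.extant_leaves()}
    induced = induce_species_tree(service_tree, all_species)
    families = [parse(fid, induced) for fid in family_ids]
    return families, induced


def fetch_family(source: str, family_id: str,
                 cache_dir: str | Path) -> tuple[ReconciledFamily, SpeciesTree]:
    families, stree = fetch_families(source, [family_id], cache_dir)
    return families[0], stree
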