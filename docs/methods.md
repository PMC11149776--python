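# Methods

## The reconciliation model

A gene family is a rooted gene tree whose nodes map onto a rooted species
tree *S*. Four events are modeled: `leaf` (extant gene), `speciation`,
`duplication`, `loss`. `transfer` labels are accepted on input and preserved
on round-trip, but laid out as speciations: a transferred lineage breaks the
"one species tree as shared axis" assumption, and no dedicated display
semantics would be meaningful under it. Multifurcating species trees are
fully supported — taxonomies from orthology databases are often unresolved —
so a speciation at a node with *k* children may have 2..*k* gene children,
and every unrepresented child becomes a loss.

Taxon assignment is the LCA of a node's extant descendant species; explicit
annotations (loss tips, implied speciations, labels carried by the input)
take precedence. For inputs without event labels, events are inferred by
**species overlap**: a node is a duplication iff the extant-species sets of
at least two children intersect. This is the standard label-free criterion
and is exactly as powerful as the data allow: a true duplication whose
surviving child lineages no longer share any species is indistinguishable
from a speciation without external information. The simulator therefore
records both the true duplication set and the *observable* one (surviving
children with overlapping spans); the inference is tested for exact equality
against the observable set, and against the full set when the loss rate is
zero (where the two coincide).

### Taxon of a duplication and subfamily origin

A duplication node's taxon is the LCA of *all* its extant descendants, and
each child subfamily *originates* at that same taxon — not at the LCA of its
own survivors. This is what routes losses correctly: if a subfamily born at
taxon *t* survives only in some deep clade, the losses between *t* and that
clade belong to the subfamily, and its profile row shows gray zeros across
the lost clades rather than outgroup blanks.

### Normalization

1. **Implied speciations.** On every parent→child edge that skips levels of
   *S*, a chain of speciation nodes is inserted, one per skipped species
   node. For a speciation parent at *t* with a child strictly below child
   *c* of *t*, the chain covers *c..parent(child's taxon)*; for a
   duplication parent the chain starts at *t* itself (the subfamily's
   origin). Inserted nodes get ids `"<anchor>@<taxon>"` where the anchor is
   the pre-existing child the chain leads to. Anchoring on the child rather
   than the parent keeps ids unique when two children of one duplication
   need chains through the same taxa.
2. **Loss tips.** Every speciation node at taxon *t* gains one loss tip per
   child of *t* with no gene child mapping into it. One tip is drawn per
   *maximal* lost clade (its label is the clade's name), not one per lost
   species — a single ancestral loss is a single event and a single row.
   Children of speciations are then ordered by species-tree position, which
   makes serializations byte-stable.

Normalization is idempotent, never changes any pre-existing node's
per-species copy counts, and its output always passes validation.
Validation itself reports every violation (node id + stable rule code)
rather than raising, so a malformed input can be diagnosed in one pass.

## The collapse view algebra

A view holds ≥1 normalized families over one species tree, a collapsed-gene
set per family, a collapsed-taxon set, and an optional root taxon (display
restricted to that clade, with families pruned and taxa above it clamped).
Three invariants are maintained after every operation: both collapsed sets
are antichains (no collapsed node below another), and every gene node whose
taxon lies inside a collapsed taxon sits at or below some collapsed gene
node (the *cascade*). Taxon collapse cascades by collapsing the topmost
displayed gene nodes inside the taxon — not by deleting them — so expanding
the taxon later restores the previous gene-tree state.

Expansion reveals speciation chains only where they lead to a duplication;
pure-speciation subtrees stay collapsed because their topology is redundant
with the species tree. Sibling subfamilies at a duplication are displayed
in descending extant-leaf count, ties broken by id; speciation children
follow species-tree order. The size-first tie-break is a deterministic
choice made here (input order would also be defensible) so that figures are
reproducible across runs and serialization round-trips.

## Profiles

Cells are computed with exact rational arithmetic (`fractions.Fraction`);
only display rounds (integers bare, otherwise one decimal — the precision
shown in a cell of ~26 px). For a row with origin taxon *t* and a column
*u*: outgroup if extant(*u*) ∩ span(*t*) = ∅, otherwise the mean copy
number over the intersection, with species lost under the row contributing
zero. A collapsed column that partially overlaps a row's span averages over
the intersection only: outgroup species carry no information about the
subfamily and must not dilute the mean. Extant-leaf tips and loss tips get
rows under the same rule (a leaf row is 1 in its species column, outgroup
elsewhere; a loss row is all zeros over its lost clade), giving uniform
one-row-per-tip semantics.

Exact arithmetic makes the averaging law testable as an identity: a
collapsed column's value equals the mean of the values the row would show
over the column's extant species.

## Rendering

Output is a pure function of (view, matrix): repeated emission is
byte-identical, which makes figures diffable and is itself a regression
test. Cell darkness is `log2(1+v)/log2(1+vmax)` — logarithmic so a single
extreme expansion darkens its column without flattening every other cell;
`vmax` is per-matrix. Branch thickness is `1+log2(n_leaves)` capped at 6
units. Lost cells are zeros on gray (`#d9d9d9`), outgroup cells blank; the
heat ramp endpoint (default `#08306b`) and clade colors are configurable as
`#rrggbb`. The HTML output is a single self-contained file: the static SVG
plus the serialized view state (collapse sets, columns, exact cell values)
embedded as JSON — a static snapshot by design, keeping output files
shareable and auditable with no scripts fetching anything.

## The synthetic-family generator

`sim.py` generates the test universe. Species trees are Yule topologies
(uniform random leaf splits) with a fixed per-edge branch length (default
1.0), which keeps the copy-number expectation closed-form:
`E[copies in s] = exp((λ−μ)·depth(s)·ℓ)`. One ancestral gene enters the
root; along each edge every lineage independently draws duplication (rate
λ) and loss (rate μ) events in continuous time; at speciations all
surviving lineages enter every child edge. The returned family is the
*observable* one — extinct lineages pruned, unary internals contracted,
taxa re-annotated by LCA of survivors — exactly what a reconstructed gene
tree shows. Ground truth shipped per family: the full event log, true and
observable duplication sets, and per-subfamily maximal lost clades computed
by direct species-tree recursion over survivor sets, an algorithm
independent of the normalization code it is used to test.

Default rates in the test suite (λ ≈ 0.15–0.35, μ ≈ 0.1–0.15 per unit
length) give families with a realistic mix of expansions, losses and
single-copy regions on trees of 5–50 species; loss-recovery checks use
λ=0, μ=0.25 where inference is provably exact.

What the generator does **not** emulate: rate heterogeneity across branches
or lineages, horizontal transfer, gene conversion, and — most importantly —
gene-tree reconstruction error. Passing tests therefore certify the view
algebra and profile arithmetic on correct reconciliations; on real data the
display is only as good as the input tree (a spurious deep duplication will
dutifully be shown as a subfamily full of loss-zeros — which is precisely
the visual signature that lets a user spot it).

## Problem sizes and numerical choices

The acceptance checks run 200 families (≤50 species) for oracle
equivalence, 500 pure-loss families for loss recovery, 100 for conservation
and collapse laws, and 2,000 replicates for calibration (3-standard-error
band around the closed form); the whole script completes in seconds. All
law checks are exact (integer/rational equality, zero tolerance); the only
stochastic quantity is the calibration ratio. Degenerate inputs: an
entirely extinct simulated family returns an explicit marker; a family
surviving in a single species is a bare leaf (no speciations, hence no
losses — consistent with the LCA origin convention); depth-limits beyond
the species-tree height are no-ops.

## Known limitations

* Unrooted trees, branch-length-aware reconciliation, and
  duplication–transfer–loss models are out of scope; the reconciliation map
  is the LCA map.
* Transfer events are preserved but displayed as speciations (see above).
* The HTML output is a static snapshot, not an interactive re-layout
  engine.
* Fetched families are imported verbatim; implausible event scenarios in
  upstream databases (e.g. deep duplications implying mass losses) are
  displayed literally, which is useful for quality control but is the
  user's call to interpret.
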