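# treematrix

Compact visualization of large gene families: a reconciled gene tree and a
species tree linked by a matrix of **phylogenetic profiles** (per-species gene
copy numbers), with species-tree-guided collapse operations that summarize
collapsed subtrees as copy-number rows instead of hiding them.

Gene trees give the complete evolutionary picture of a family but become
unreadable at hundreds of species; phylogenetic profiles scale but lose the
evolutionary relationships (two absences may be one ancestral loss or two
independent ones). `treematrix` bridges the two: collapsing a subtree keeps
its per-species copy-number distribution visible as a matrix row, so no
information is lost. It is aimed at comparative genomicists studying gene
repertoire evolution (duplications, losses, lineage-specific expansions) and
at anyone producing figures of large families.

## The model

A family is a rooted gene tree reconciled with a rooted (possibly
multifurcating) species tree *S*: every gene node carries an event label
(leaf, speciation, duplication, loss) and a *taxon* — the node of *S* where
the lineage resided, computed as the LCA of its extant descendants unless
given explicitly. Consistency means speciations follow the same order in
both trees; this is what lets one species tree serve as the shared column
axis for any number of families.

**Normalization** makes the reconciliation explicit: speciation nodes are
inserted on edges that skip levels of *S*, and one loss tip is attached per
maximal species clade a speciation leaves unrepresented ("losses implied
from the species tree").

**Collapse algebra.** Four named behaviors over a view state:

* *Smart Collapse* — collapse every maximal duplication-free subtree. The
  result is information-equivalent to the full tree: a duplication-free
  subtree's topology is explicit in the species tree.
* *Collapse All* — one profile row per family (its root).
* *Expand* — unfolding a collapsed node reveals topology only until the next
  duplication nodes, which define the child subfamilies.
* *Taxon collapse* (and *auto-collapse at depth d*) — collapsing a clade of
  *S* merges its columns and cascades to the gene trees; the merged cell
  shows the **average number of in-paralogs** over the clade's species.

**Profile cells.** For a row with origin taxon *t* (where the subfamily
arose) and a column *u* with extant species set *L(u)*:

```
I = L(u) ∩ span(t);   I = ∅  →  OUTGROUP (blank)
value = ( Σ_{s∈I} copies(s) ) / |I|;   value = 0 → LOST (gray zero)
```

Species lost under the row contribute zeros to the mean; outgroup species
never count. Arithmetic is exact (rationals); display rounds to one decimal.

## Worked example

The toy species tree is `((A,B)AB,C)R`. Family F2 duplicated at the root
`R`: subfamily X kept one gene in each species, subfamily Y survived only as
one gene in species A.

```python
from treematrix import (init_view, smart_collapse, collapse_taxon,
                        profile_matrix, matrix_to_tsv, normalize,
                        family_from_json, read_species_newick)

stree = read_species_newick("((A,B)AB,C)R;")
f2 = family_from_json(open("f2.json").read(), stree)
normalize(f2)
state = smart_collapse(init_view([f2], stree))
print(matrix_to_tsv(profile_matrix(state)))
```

prints

```
label	origin_taxon	A	B	C
X	R	1	1	1
R	R	1	0	0
```

Row X: one copy in every species. The second row is subfamily Y; because it
arose at the root duplication (origin taxon `R`), its zeros in B and C are
*losses* (drawn as gray zeros in SVG/HTML), not outgroup blanks. Collapsing
the taxon `AB` (`collapse_taxon(state, stree.index["AB"])`) merges the A and
B columns and averages: Y's cell becomes `0.5` — the mean of one copy in A
and zero in B.

The same run from the shell:

```sh
treematrix --json f2.json --species s.nwk --out view.html --svg view.svg \
           --export-tsv profiles.tsv
```

`--collapse-all`, `--collapse-depth N`, `--root-taxon NAME`,
`--color TAXON=#hex` and `--oma/--panther ID[,ID...]` (cached under
`--cache`) select the view and data source; multiple families stack over the
shared columns.

## Layout

```
src/treematrix/
  model.py      domain types, taxon annotation, event inference, validation
  reconcile.py  implied speciations, loss tips, copy-count oracle, skeleton
  view.py       the collapse view algebra
  profiles.py   profile matrices, averaging, TSV export
  io.py         newick / JSON / orthoXML readers, cached OMA & PANTHER fetch
  render.py     deterministic SVG and self-contained HTML
  sim.py        birth–death family generator with ground-truth event logs
  cli.py        command-line entry point
```

See `docs/methods.md` for the algorithmic details and design choices.
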