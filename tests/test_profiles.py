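"""Profile matrices: copy-number cells, loss-zeros, outgroup-empties and
in-paralog averaging under taxon collapse."""

import random
from fractions import Fraction

import pytest

from treematrix.model import GeneNode, ReconciledFamily, annotate_taxa
from treematrix.profiles import (
    CellKind,
    matrix_to_tsv,
    profile_matrix,
    profile_row,
)
from treematrix.reconcile import leaf_counts, normalize
from treematrix.sim import SimConfig, simulate_family, simulate_species_tree
from treematrix.view import (
    collapse_all,
    collapse_taxon,
    init_view,
    smart_collapse,
    visible_columns,
    visible_tips,
)

from conftest import make_leaf


def _cells(row):
    return [(c.kind, c.value) for c in row.cells]


class TestProfileRow:
    def test_subfamily_y_spans_root_with_loss_zeros(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        tips = {t.id: t for t in visible_tips(state, f2)}
        row = profile_row(tips["a2@R"], state)
        assert _cells(row) == [(CellKind.COUNT, 1), (CellKind.LOST, 0),
                               (CellKind.LOST, 0)]

    def test_subfamily_x_full_span(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        tips = {t.id: t for t in visible_tips(state, f2)}
        row = profile_row(tips["X"], state)
        assert _cells(row) == [(CellKind.COUNT, 1)] * 3

    def test_outgroup_cells_exactly_off_span(self, stree, f2):
        # a tip whose origin is AB leaves column C empty (outgroup), which is
        # distinct from a loss-zero
        state = init_view([f2], stree)
        xab = f2.node_index()["xab"]
        row = profile_row(xab, state)
        assert [c.kind for c in row.cells] == \
            [CellKind.COUNT, CellKind.COUNT, CellKind.OUTGROUP]

    def test_averaging_over_collapsed_column(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_taxon(state, stree.index["AB"])
        tips = {t.id: t for t in visible_tips(state, f2)}
        row = profile_row(tips["a2@R"], state)
        # mean over {A: 1, B: 0} = 1/2; C is a plain loss
        assert _cells(row) == [(CellKind.COUNT, Fraction(1, 2)), (CellKind.LOST, 0)]

    def test_extant_leaf_row(self, stree, f1):
        state = init_view([f1], stree)
        row = profile_row(f1.node_index()["b1"], state)
        assert [c.kind for c in row.cells] == \
            [CellKind.OUTGROUP, CellKind.COUNT, CellKind.OUTGROUP]
        assert row.cells[1].value == 1

    def test_loss_tip_row_all_lost_over_its_clade(self, stree, f2):
        state = init_view([f2], stree)
        loss = next(n for n in f2.nodes()
                    if n.event == "loss" and n.taxon.name == "B")
        row = profile_row(loss, state)
        assert _cells(row) == [(CellKind.OUTGROUP, 0), (CellKind.LOST, 0),
                               (CellKind.OUTGROUP, 0)]

    def test_display_rounding(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_taxon(state, stree.index["AB"])
        tips = {t.id: t for t in visible_tips(state, f2)}
        row = profile_row(tips["a2@R"], state)
        assert row.cells[0].display() == "0.5"  # one decimal for fractions
        full = profile_row(tips["X"], state)
        assert full.cells[0].display() == "1"   # integers bare


class TestProfileMatrix:
    def test_collapse_all_stacks_families_over_shared_columns(self, stree, f1, f2):
        state = collapse_all(init_view([f1, f2], stree))
        matrix = profile_matrix(state)
        assert matrix.shape == (2, 3)
        assert [c.value for c in matrix.rows[1].cells] == [2, 1, 1]
        assert matrix.vmax == 2

    def test_smart_collapse_rows(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        matrix = profile_matrix(state)
        assert matrix.shape == (2, 3)
        assert [c.value for c in matrix.rows[0].cells] == [1, 1, 1]
        kinds = [c.kind for c in matrix.rows[1].cells]
        assert kinds == [CellKind.COUNT, CellKind.LOST, CellKind.LOST]

    def test_tsv_export(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_taxon(state, stree.index["AB"])
        tsv = matrix_to_tsv(profile_matrix(state))
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t") == ["label", "origin_taxon", "AB", "C"]
        assert lines[2].split("\t")[2:] == ["0.5", "0"]  # LOST written as 0

    def test_outgroup_exported_as_empty_string(self, stree, f1):
        state = init_view([f1], stree)
        tsv = matrix_to_tsv(profile_matrix(state))
        row_b = [l for l in tsv.split("\n") if l.startswith("b1")][0]
        assert row_b.split("\t")[2:] == ["", "1", ""]


class TestOracleEquivalence:
    def test_cells_equal_leaf_count_oracle_on_simulations(self):
        checked = 0
        for seed in range(1, 41):
            stree = simulate_species_tree(12, seed)
            sim = simulate_family(stree, SimConfig(0.3, 0.15, seed))
            if sim.extinct:
                continue
            normalize(sim.family)
            state = smart_collapse(init_view([sim.family], stree))
            matrix = profile_matrix(state)
            for row in matrix.rows:
                counts = leaf_counts(row.tip)
                span = stree.leaf_set(row.origin_taxon)
                for column, cell in zip(matrix.columns, row.cells):
                    name = column.name
                    if name not in span:
                        assert cell.kind is CellKind.OUTGROUP
                    else:
                        assert cell.value == counts.get(name, 0)
                        checked += 1
        assert checked > 100

    def test_conservation_under_expansion(self):
        # per species, children rows at a duplication sum to the parent row
        for seed in range(1, 21):
            stree = simulate_species_tree(10, seed)
            sim = simulate_family(stree, SimConfig(0.35, 0.1, seed))
            if sim.extinct:
                continue
            normalize(sim.family)
            for node in sim.family.nodes():
                if node.event != "duplication":
                    continue
                parent_counts = leaf_counts(node)
                summed = {}
                for child in node.children:
                    for sp, k in leaf_counts(child).items():
                        summed[sp] = summed.get(sp, 0) + k
                assert summed == dict(parent_counts)

    def test_averaging_law_on_random_collapse_states(self):
        # a collapsed column's value equals the mean of the values the row
        # would have over its extant columns (loss-zeros in, outgroups out)
        for seed in range(1, 21):
            stree = simulate_species_tree(12, seed)
            sim = simulate_family(stree, SimConfig(0.3, 0.15, seed))
            if sim.extinct:
                continue
            normalize(sim.family)
            rng = random.Random(seed)
            state = smart_collapse(init_view([sim.family], stree))
            flat = profile_matrix(state)
            base = {}
            for row in flat.rows:
                for column, cell in zip(flat.columns, row.cells):
                    base[(row.tip.id, column.name)] = cell
            internal = [n for n in stree.preorder() if not n.is_leaf]
            for taxon in rng.sample(internal, min(3, len(internal))):
                try:
                    collapse_taxon(state, taxon)
                except Exception:
                    continue
            matrix = profile_matrix(state)
            for row in matrix.rows:
                for column, cell in zip(matrix.columns, row.cells):
                    if column.is_leaf:
                        continue
                    members = [base.get((row.tip.id, s))
                               for s in stree.leaf_set(column)]
                    members = [m for m in members
                               if m is not None and m.kind is not CellKind.OUTGROUP]
                    if not members:
                        # row tip may itself have been collapsed away; values
                        # for merged tips are checked via the oracle instead
                        counts = leaf_counts(row.tip)
                        span = stree.leaf_set(row.origin_taxon)
                        inter = stree.leaf_set(column) & span
                        if not inter:
                            assert cell.kind is CellKind.OUTGROUP
                        else:
                            expected = Fraction(
                                sum(counts.get(s, 0) for s in inter), len(inter))
                            assert cell.value == expected
                        continue
                    expected = Fraction(sum(m.value for m in members), len(members))
                    assert cell.value == expected
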