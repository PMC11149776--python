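"""The collapse view algebra: smart collapse, collapse all, expansion to the
next duplication, taxon collapse cascade and depth auto-collapse."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treematrix.model import (
    GeneNode,
    ReconciledFamily,
    TreeMatrixError,
    annotate_taxa,
    infer_events,
)
from treematrix.reconcile import normalize
from treematrix.sim import SimConfig, simulate_family, simulate_species_tree
from treematrix.view import (
    auto_collapse_depth,
    collapse_all,
    collapse_node,
    collapse_taxon,
    expand_node,
    init_view,
    smart_collapse,
    visible_columns,
    visible_tips,
)

from conftest import build_f1, build_f2, make_leaf


def _sim_view(seed, n_species=12, lam=0.3, mu=0.15):
    stree = simulate_species_tree(n_species, seed)
    sim = simulate_family(stree, SimConfig(lam, mu, seed))
    if sim.extinct:
        return None
    normalize(sim.family)
    return init_view([sim.family], stree)


class TestInitView:
    def test_empty_collapse_sets_and_columns(self, stree, f1, f2):
        state = init_view([f1, f2], stree)
        assert all(not ids for ids in state.collapsed_genes.values())
        assert [c.name for c in visible_columns(state)] == ["A", "B", "C"]

    def test_families_must_share_species_tree(self, stree, f1):
        from treematrix.io import read_species_newick
        other = read_species_newick("((A,B)AB,C)R;")
        foreign = build_f2(other)
        with pytest.raises(TreeMatrixError):
            init_view([f1, foreign], stree)

    def test_root_taxon_prunes_families_and_columns(self, stree, f2):
        state = init_view([f2], stree, root_taxon="AB")
        assert [c.name for c in visible_columns(state)] == ["A", "B"]
        ids = {n.id for n in state.families[0].nodes()}
        assert "xc1" not in ids  # the C leaf is gone
        assert not any("loss%C" in i for i in ids)  # and the C loss with it
        # subfamily Y is now a span-A subtree below AB
        assert "a2@AB" in ids and "a2@R" not in ids

    def test_unknown_root_taxon_errors(self, stree, f2):
        with pytest.raises(TreeMatrixError):
            init_view([f2], stree, root_taxon="Z")


class TestSmartCollapse:
    def test_duplication_free_family_collapses_to_root(self, stree, f1):
        state = smart_collapse(init_view([f1], stree))
        assert [t.id for t in visible_tips(state, f1)] == ["F1root"]

    def test_f2_shows_two_subfamily_rows(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        assert [t.id for t in visible_tips(state, f2)] == ["X", "a2@R"]

    def test_idempotent(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        snapshot = {fid: set(ids) for fid, ids in state.collapsed_genes.items()}
        smart_collapse(state)
        assert state.collapsed_genes == snapshot

    def test_minimality_on_simulations(self):
        # every collapsed subtree is duplication-free and every displayed
        # internal node subtends a duplication
        for seed in range(1, 31):
            state = _sim_view(seed)
            if state is None:
                continue
            smart_collapse(state)
            family = state.families[0]
            cache = state.cache(family)
            for node_id in state.collapsed_genes[family.family_id]:
                assert not cache.has_dup[node_id]
            from treematrix.view import displayed_internal_nodes
            for node in displayed_internal_nodes(state, family):
                assert cache.has_dup[node.id]


class TestCollapseAll:
    def test_one_row_per_family(self, stree, f1, f2):
        state = collapse_all(init_view([f1, f2], stree))
        assert [t.id for t in visible_tips(state, f1)] == ["F1root"]
        assert [t.id for t in visible_tips(state, f2)] == ["F2root"]

    def test_idempotent(self, stree, f2):
        state = collapse_all(init_view([f2], stree))
        collapse_all(state)
        assert state.collapsed_genes["F2"] == {"F2root"}


class TestExpandNode:
    def test_expanding_root_of_collapse_all_equals_smart_for_f2(self, stree, f2):
        state = collapse_all(init_view([f2], stree))
        expand_node(state, f2, f2.root)
        smart = smart_collapse(init_view([build_f2(stree)], stree))
        assert state.collapsed_genes["F2"] == smart.collapsed_genes["F2"]

    def test_nested_duplication_stays_hidden(self, stree):
        # root duplication with child X' that is itself a duplication holding
        # a further duplication: expanding the root collapses X' whole (it is
        # a topmost duplication); the inner one only appears once X' is
        # expanded in turn
        inner = GeneNode("inner", "duplication",
                         children=[make_leaf(stree, "ia1", "A"),
                                   make_leaf(stree, "ia2", "A")])
        xprime = GeneNode("xp", "duplication",
                          children=[inner, make_leaf(stree, "ia3", "A")])
        root = GeneNode("root", "duplication",
                        children=[xprime, make_leaf(stree, "y", "B")])
        fam = ReconciledFamily("nested", root, stree)
        annotate_taxa(fam)
        normalize(fam)
        state = collapse_all(init_view([fam], stree))
        expand_node(state, fam, fam.root)
        collapsed = state.collapsed_genes["nested"]
        assert "xp" in collapsed and "inner" not in collapsed
        # later expanding X' reveals the inner duplication as its own subfamily
        expand_node(state, fam, xprime)
        assert "inner" in state.collapsed_genes["nested"]

    def test_expand_non_collapsed_warns_and_is_noop(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        with pytest.warns(UserWarning):
            expand_node(state, f2, f2.root)

    def test_round_trip_with_collapse_node(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        tips_before = [t.id for t in visible_tips(state, f2)]
        collapse_node(state, f2, f2.root)
        assert [t.id for t in visible_tips(state, f2)] == ["F2root"]
        expand_node(state, f2, f2.root)
        assert [t.id for t in visible_tips(state, f2)] == tips_before


class TestCollapseNode:
    def test_collapse_displayed_root_equals_collapse_all(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_node(state, f2, f2.root)
        assert state.collapsed_genes["F2"] == {"F2root"}

    def test_collapse_hidden_node_errors(self, stree, f2):
        state = collapse_all(init_view([f2], stree))
        hidden = f2.node_index()["xab"]
        with pytest.raises(TreeMatrixError):
            collapse_node(state, f2, hidden)

    def test_collapse_extant_leaf_gives_single_gene_row(self, stree, f2):
        state = init_view([f2], stree)
        collapse_node(state, f2, f2.node_index()["a2"])
        assert "a2" in state.collapsed_genes["F2"]
        assert "a2" in [t.id for t in visible_tips(state, f2)]

    def test_idempotent(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_node(state, f2, f2.node_index()["X"])
        snapshot = set(state.collapsed_genes["F2"])
        collapse_node(state, f2, f2.node_index()["X"])
        assert state.collapsed_genes["F2"] == snapshot


class TestCollapseTaxon:
    def test_columns_merge_and_gene_nodes_cascade(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_taxon(state, stree.index["AB"])
        assert [c.name for c in visible_columns(state)] == ["AB", "C"]
        # no displayed gene structure below AB remains
        for tip in visible_tips(state, f2):
            assert not (stree.is_ancestor_or_self(stree.index["AB"], tip.taxon)
                        and tip.taxon is not stree.index["AB"]) or tip.is_tip

    def test_collapse_root_taxon_collapses_every_family(self, stree, f1, f2):
        state = smart_collapse(init_view([f1, f2], stree))
        collapse_taxon(state, stree.index["R"])
        assert [c.name for c in visible_columns(state)] == ["R"]
        assert [t.id for t in visible_tips(state, f1)] == ["F1root"]
        assert [t.id for t in visible_tips(state, f2)] == ["F2root"]

    def test_extant_taxon_errors(self, stree, f2):
        state = init_view([f2], stree)
        with pytest.raises(TreeMatrixError):
            collapse_taxon(state, stree.index["A"])

    def test_idempotent(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        collapse_taxon(state, stree.index["AB"])
        taxa = set(state.collapsed_taxa)
        genes = {f: set(s) for f, s in state.collapsed_genes.items()}
        collapse_taxon(state, stree.index["AB"])
        assert state.collapsed_taxa == taxa and state.collapsed_genes == genes


class TestAutoCollapseDepth:
    @pytest.mark.parametrize("depth, expected", [
        (1, ["AB", "C"]),
        (0, ["R"]),
        (5, ["A", "B", "C"]),  # beyond tree height: no change
    ])
    def test_column_sets(self, stree, f2, depth, expected):
        state = smart_collapse(init_view([f2], stree))
        auto_collapse_depth(state, depth)
        assert [c.name for c in visible_columns(state)] == expected

    def test_idempotent(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        auto_collapse_depth(state, 1)
        taxa = set(state.collapsed_taxa)
        auto_collapse_depth(state, 1)
        assert state.collapsed_taxa == taxa


class TestVisibleTips:
    def test_duplication_children_ordered_by_size_then_id(self, stree, f2):
        state = smart_collapse(init_view([f2], stree))
        assert [t.id for t in visible_tips(state, f2)] == ["X", "a2@R"]

    def test_fully_expanded_family_in_species_order(self, stree, f1):
        state = init_view([f1], stree)
        assert [t.id for t in visible_tips(state, f1)] == ["a1", "b1", "c1"]


def _cascade_holds(state):
    stree = state.species_tree
    hidden = [stree.index[t] for t in state.collapsed_taxa]
    for family in state.families:
        collapsed = state.collapsed_genes[family.family_id]
        # antichain
        for cid in collapsed:
            node = family.node_index()[cid]
            strict = {n.id for n in node.walk()} - {cid}
            assert not (strict & collapsed)
        # cascade
        def visit(node, under_collapsed):
            under = under_collapsed or node.id in collapsed
            if node.taxon is not None and any(
                    stree.is_ancestor_or_self(h, node.taxon) for h in hidden):
                assert under
            for child in node.children:
                visit(child, under)
        visit(family.root, False)
    # collapsed taxa form an antichain
    for a in hidden:
        for b in hidden:
            if a is not b:
                assert not stree.is_ancestor_or_self(a, b)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=1, max_value=500),
       ops=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=12))
def test_cascade_invariant_under_random_operation_sequences(seed, ops):
    """Collapsed sets stay antichains and the taxon-collapse cascade holds
    after arbitrary operation sequences."""
    state = _sim_view(seed)
    if state is None:
        return
    rng = random.Random(seed)
    family = state.families[0]
    index = family.node_index()
    internal_taxa = [n for n in state.species_tree.preorder() if not n.is_leaf]
    for op in ops:
        if op == 0:
            smart_collapse(state)
        elif op == 1:
            collapse_all(state)
        elif op == 2:
            collapsed = state.collapsed_genes[family.family_id]
            if collapsed:
                node = index[rng.choice(sorted(collapsed))]
                expand_node(state, family, node)
        elif op == 3:
            candidates = [n for n in index.values() if not n.is_tip]
            if not candidates:
                continue
            node = rng.choice(sorted(candidates, key=lambda n: n.id))
            try:
                collapse_node(state, family, node)
            except TreeMatrixError:
                pass
        elif op == 4:
            taxon = rng.choice(internal_taxa)
            try:
                collapse_taxon(state, taxon)
            except TreeMatrixError:
                pass
        else:
            auto_collapse_depth(state, rng.randrange(0, 5))
        _cascade_holds(state)
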