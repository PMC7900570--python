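"""Role propagation: conflict rules, edge-once traversal, stop rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrpath.arr_annotator import (
    ARR_VALUES,
    annotate_pathway,
    propagate_arr,
    propose_arr,
    resolve_conflict,
)
from arrpath.pathway_model import (
    AnnotationConfig,
    Edge,
    EdgeType,
    Pathway,
    PathwayError,
)
from arrpath.synthetic_fixtures import generate_cyclic_pathway, generate_signed_tree

from conftest import make_node, make_pathway, path_sign_oracle


class TestResolveConflict:
    @pytest.mark.parametrize(
        "previous, proposed, expected",
        [
            (1, -1, 0),        # opposite signs -> inconsistent
            (-1, 1, 0),
            (0.5, -1, 0),
            (-0.5, 1, 0),
            (0.5, 1, 0.5),     # within 0.5, positive side -> rather activator
            (1, 0.5, 0.5),
            (-0.5, -1, -0.5),  # within 0.5, negative side -> rather repressor
            (-1, -0.5, -0.5),
            (1, 1, 1),         # agreement keeps the role
            (-1, -1, -1),
            (0, 0, 0),
            (0, 1, 0),         # sticky zero: gap exceeds 0.5
            (0, -1, 0),
            (0, 0.5, 0.5),     # zero vs half-role is within 0.5
            (0, -0.5, -0.5),
        ],
    )
    def test_resolution_table(self, previous, proposed, expected):
        assert resolve_conflict(previous, proposed) == expected

    def test_illegal_value_rejected(self):
        with pytest.raises(PathwayError):
            resolve_conflict(0.7, 1)

    @given(
        prev=st.sampled_from(sorted(ARR_VALUES)),
        prop=st.sampled_from(sorted(ARR_VALUES)),
    )
    def test_closure_over_legal_values(self, prev, prop):
        assert resolve_conflict(prev, prop) in ARR_VALUES


class TestProposeArr:
    def test_activation_carries_source_sign(self):
        assert propose_arr(1, EdgeType.ACTIVATION) == 1
        assert propose_arr(-1, EdgeType.ACTIVATION) == -1

    def test_inhibition_flips_source_sign(self):
        assert propose_arr(1, EdgeType.INHIBITION) == -1

    def test_double_negation_differs_between_modes(self):
        multiplicative = AnnotationConfig(propagation="multiplicative")
        edge_only = AnnotationConfig(propagation="edge_only")
        assert propose_arr(-1, EdgeType.INHIBITION, multiplicative) == 1
        assert propose_arr(-1, EdgeType.INHIBITION, edge_only) == -1

    def test_expanding_stopped_node_is_internal_error(self):
        with pytest.raises(PathwayError):
            propose_arr(0.5, EdgeType.ACTIVATION)


class TestAnnotation:
    def test_star_all_activation(self, star_pathway):
        ann = annotate_pathway(star_pathway)
        assert ann.central_node == "H"
        assert ann.gene_arr["G_H"] == 1
        assert all(ann.gene_arr[f"G_L{i}"] == 1 for i in range(4))
        assert ann.excluded_genes == set()

    def test_star_with_one_inhibition_leaf(self):
        pw = make_pathway(
            "star2",
            [("H", "G_H"), ("X", "G_X"), ("Y", "G_Y"), ("Z", "G_Z")],
            [("H", "X", "inhibition"), ("H", "Y", "activation"),
             ("H", "Z", "activation")],
        )
        ann = annotate_pathway(pw)
        assert ann.gene_arr["G_X"] == -1
        assert ann.gene_arr["G_Y"] == ann.gene_arr["G_Z"] == 1

    def test_diamond_reconvergence_resolves_to_zero(self, diamond_pathway):
        for mode in ("multiplicative", "edge_only"):
            ann = annotate_pathway(
                diamond_pathway, AnnotationConfig(propagation=mode)
            )
            assert ann.gene_arr["G_T"] == 0, mode

    @pytest.mark.parametrize("seed", range(20))
    def test_tree_roles_match_path_sign_oracle(self, seed):
        pw, truth = generate_signed_tree(30, 0.5, seed)
        ann = annotate_pathway(pw)
        assert ann.central_node == "r"  # root maximises N+M on an out-tree
        oracle = path_sign_oracle(pw, "r")
        assert oracle == truth
        for node_id, role in truth.items():
            assert ann.node_arr[node_id] == role
            (gene,) = pw.node(node_id).genes
            assert ann.gene_arr[gene] == role

    def test_single_edge_flip_negates_exactly_its_subtree(self):
        # roles are path-sign products, so flipping one edge negates the
        # roles of precisely the nodes below it and no others
        pw, _ = generate_signed_tree(25, 0.4, seed=11)
        flip_index = 7
        flipped_edges = [
            Edge(e.source, e.target,
                 EdgeType.INHIBITION if e.etype is EdgeType.ACTIVATION
                 else EdgeType.ACTIVATION)
            if i == flip_index else e
            for i, e in enumerate(pw.edges)
        ]
        flipped = Pathway(name=pw.name, nodes=list(pw.nodes), edges=flipped_edges)

        children: dict[str, list[str]] = {}
        for e in pw.edges:
            children.setdefault(e.source, []).append(e.target)
        subtree, stack = set(), [pw.edges[flip_index].target]
        while stack:
            v = stack.pop()
            subtree.add(v)
            stack.extend(children.get(v, ()))

        ann, ann_flipped = annotate_pathway(pw), annotate_pathway(flipped)
        for node_id in pw.node_ids:
            expected = -ann.node_arr[node_id] if node_id in subtree else ann.node_arr[node_id]
            assert ann_flipped.node_arr[node_id] == expected

    @pytest.mark.parametrize("n", [3, 10, 50, 100])
    def test_cycle_terminates_within_edge_budget(self, n):
        pw = generate_cyclic_pathway(n, seed=n)
        ann = annotate_pathway(pw)
        edge_events = [t for t in ann.trace if t.edge_index >= 0]
        assert len(edge_events) <= len(pw.edges)
        assert len({t.edge_index for t in edge_events}) == len(edge_events)

    def test_all_values_legal_and_central_is_one(self):
        for seed in range(10):
            pw, _ = generate_signed_tree(15, 0.5, seed)
            ann = annotate_pathway(pw)
            assert ann.node_arr[ann.central_node] == 1
            assert set(ann.node_arr.values()) <= ARR_VALUES
            assert set(ann.gene_arr.values()) <= ARR_VALUES

    def test_rerun_gives_byte_identical_trace(self, diamond_pathway):
        a = annotate_pathway(diamond_pathway)
        b = annotate_pathway(diamond_pathway)
        assert [t.as_line() for t in a.trace] == [t.as_line() for t in b.trace]
        assert a.gene_arr == b.gene_arr

    def test_modes_agree_at_distance_one(self, star_pathway):
        m = annotate_pathway(star_pathway, AnnotationConfig(propagation="multiplicative"))
        e = annotate_pathway(star_pathway, AnnotationConfig(propagation="edge_only"))
        assert m.node_arr == e.node_arr

    def test_genes_past_stopped_node_are_excluded(self):
        # A and B propose opposite roles to T; T resolves to 0 and is not
        # expanded, so U behind T stays unreached.
        pw = make_pathway(
            "blocked",
            [("C", "G_C"), ("A", "G_A"), ("B", "G_B"), ("T", "G_T"), ("U", "G_U")],
            [("C", "A", "activation"), ("C", "B", "inhibition"),
             ("A", "T", "activation"), ("B", "T", "activation"),
             ("T", "U", "activation")],
        )
        ann = annotate_pathway(pw)
        assert ann.node_arr["T"] == 0
        assert "G_U" in ann.excluded_genes
        assert "G_U" not in ann.gene_arr

    def test_disconnected_requires_per_component(self):
        pw = make_pathway("two", [(x, f"G_{x}") for x in "abcd"],
                          [("a", "b"), ("c", "d")])
        with pytest.raises(PathwayError, match="component"):
            annotate_pathway(pw)
        ann = annotate_pathway(pw, AnnotationConfig(per_component=True))
        assert set(ann.gene_arr) == {"G_a", "G_b", "G_c", "G_d"}

    def test_undefined_edge_policies(self):
        pw = make_pathway("u", [("a", "G_A"), ("b", "G_B")],
                          [("a", "b", "undefined")])
        passed = annotate_pathway(pw)
        assert passed.gene_arr["G_B"] == 1
        skipped = annotate_pathway(
            pw, AnnotationConfig(undefined_edge_policy="skip")
        )
        assert "G_B" in skipped.excluded_genes

    def test_multi_gene_node_assigns_every_member(self):
        pw = Pathway(
            "multi",
            nodes=[
                make_node("a", "G_A"),
                type(make_node("b"))(node_id="b", genes=frozenset({"X", "Y"})),
            ],
            edges=[Edge("a", "b", "inhibition")],
        )
        ann = annotate_pathway(pw)
        assert ann.gene_arr["X"] == ann.gene_arr["Y"] == -1


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_annotation_total_on_trees_property(seed):
    """On any signed out-tree every gene is annotated, none excluded."""
    pw, truth = generate_signed_tree(12, 0.3, seed)
    ann = annotate_pathway(pw)
    assert ann.excluded_genes == set()
    assert len(ann.gene_arr) == len(pw.all_genes)
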