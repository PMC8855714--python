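"""Expression generation: forms, count laws, and oracle equivalence."""

import itertools

import pytest

from phyx import (
    And,
    ExcludesTU,
    HasAncestor,
    HasChild,
    IncludesTU,
    Phyloreference,
    TaxonomicUnit,
    annotate,
    evaluate,
    expr_one_internal_one_external,
    expr_two_internals,
    max_clade_components,
    min_clade_components,
    oracle_max_clade,
    oracle_min_clade,
    phyloref_to_components,
    write_newick,
)
from phyx.clade_expressions import SpecifierArityError, UnsupportedPhylorefType
from phyx.phyx_document import Phylogeny


def tu(letter: str) -> TaxonomicUnit:
    return TaxonomicUnit.from_name(letter)


def annotated(tree):
    """Annotate a letter-leaf topology via its Newick form."""
    return annotate(Phylogeny(newick=write_newick(tree)))


def leaf_ids(at):
    return {node.label: node.node_id for node in at.tree.leaves()}


def union_eval(component_set, at):
    out = set()
    for expr in component_set.components:
        out |= evaluate(expr, at)
    return out


class TestExpressionForms:
    def test_one_internal_one_external_shape(self):
        expr = expr_one_internal_one_external(tu("A"), tu("C"))
        assert isinstance(expr, And)
        assert {type(op) for op in expr.operands} == {IncludesTU, ExcludesTU}

    def test_two_internals_shape(self):
        expr = expr_two_internals(tu("A"), tu("B"))
        assert isinstance(expr, HasChild)
        assert isinstance(expr.expr, And)

    def test_min_n2_identical_to_two_internal_expression(self):
        comp = min_clade_components([tu("A"), tu("B")])
        assert len(comp.components) == 1
        assert comp.components[0] == expr_two_internals(tu("A"), tu("B"))

    def test_max_single_external_identical_to_simple_expression(self):
        comp = max_clade_components([tu("A")], [tu("C")])
        assert len(comp.components) == 1
        assert comp.components[0] == expr_one_internal_one_external(tu("A"), tu("C"))

    def test_max_other_externals_use_has_ancestor(self):
        comp = max_clade_components([tu("A")], [tu("C"), tu("D")])
        for component in comp.components:
            assert sum(isinstance(op, HasAncestor) for op in component.operands) == 1


class TestCountLaws:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_min_clade_component_count(self, n):
        internals = [tu(letter) for letter in "ABCDE"[:n]]
        comp = min_clade_components(internals)
        assert len(comp.components) == n * (n - 1) // 2

    @pytest.mark.parametrize("n_ext", [1, 2, 3, 4])
    def test_max_clade_component_count(self, n_ext):
        externals = [tu(letter) for letter in "CDEF"[:n_ext]]
        comp = max_clade_components([tu("A"), tu("B")], externals)
        assert len(comp.components) == n_ext

    def test_arity_errors(self):
        with pytest.raises(SpecifierArityError):
            min_clade_components([tu("A")])
        with pytest.raises(SpecifierArityError):
            max_clade_components([tu("A")], [])
        with pytest.raises(SpecifierArityError):
            max_clade_components([], [tu("C")])


class TestDispatch:
    def test_minimum_clade(self):
        p = Phyloreference(definition="d", phyloref_type="minimum-clade",
                           internal_specifiers=[tu("A"), tu("B")])
        assert len(phyloref_to_components(p).components) == 1

    def test_maximum_clade(self):
        p = Phyloreference(definition="d", phyloref_type="maximum-clade",
                           internal_specifiers=[tu("A")],
                           external_specifiers=[tu("C")])
        assert len(phyloref_to_components(p).components) == 1

    def test_minimum_clade_one_internal_one_external_falls_back(self):
        p = Phyloreference(definition="d", phyloref_type="minimum-clade",
                           internal_specifiers=[tu("A")],
                           external_specifiers=[tu("C")])
        assert phyloref_to_components(p).components == \
            max_clade_components([tu("A")], [tu("C")]).components

    def test_apomorphy_unsupported(self):
        p = Phyloreference(definition="d", phyloref_type="apomorphy-based",
                           internal_specifiers=[tu("A")])
        with pytest.raises(UnsupportedPhylorefType):
            phyloref_to_components(p)


class TestWorkedExamples:
    def test_one_internal_one_external_on_nested_tree(self):
        at = annotated_from("(((A,B),C),D);")
        ids = leaf_ids(at)
        expr = expr_one_internal_one_external(tu("A"), tu("C"))
        resolved = evaluate(expr, at)
        expected = oracle_min_clade(
            [at.tree.node(ids["A"]), at.tree.node(ids["B"])], at.tree)
        assert resolved == {expected.node_id}

    def test_one_internal_one_external_resolves_leaf(self):
        at = annotated_from("((A,C),B);")
        ids = leaf_ids(at)
        expr = expr_one_internal_one_external(tu("A"), tu("C"))
        assert evaluate(expr, at) == {ids["A"]}

    def test_two_internals_resolves_mrca(self):
        at = annotated_from("(((A,B),C),D);")
        ids = leaf_ids(at)
        expr = expr_two_internals(tu("A"), tu("B"))
        expected = oracle_min_clade(
            [at.tree.node(ids["A"]), at.tree.node(ids["B"])], at.tree)
        assert evaluate(expr, at) == {expected.node_id}

    def test_two_internals_of_everything_resolves_root(self):
        at = annotated_from("(A,B);")
        expr = expr_two_internals(tu("A"), tu("B"))
        assert evaluate(expr, at) == {at.tree.root.node_id}

    def test_max_clade_two_externals_on_nested_tree(self):
        at = annotated_from("(((A,B),C),D);")
        ids = leaf_ids(at)
        comp = max_clade_components([tu("A")], [tu("C"), tu("D")])
        expected = oracle_max_clade(
            [at.tree.node(ids["A"])],
            [at.tree.node(ids["C"]), at.tree.node(ids["D"])],
            at.tree)
        assert union_eval(comp, at) == {expected.node_id}


def annotated_from(newick):
    return annotate(Phylogeny(newick=newick))


class TestOracleEquivalence:
    """The central property: expressions agree with the direct clade oracles."""

    def test_min_clade_pairs_exhaustive(self, small_catalogs):
        for catalog in small_catalogs.values():
            for tree in catalog.topologies:
                at = annotated(tree)
                ids = leaf_ids(at)
                for a, b in itertools.combinations(sorted(ids), 2):
                    comp = min_clade_components([tu(a), tu(b)])
                    expected = oracle_min_clade(
                        [at.tree.node(ids[a]), at.tree.node(ids[b])], at.tree)
                    assert union_eval(comp, at) == {expected.node_id}, \
                        f"min {{{a},{b}}} on {at.tree.source_newick}"

    def test_min_clade_three_internals_exhaustive(self, catalogs):
        """Three-internal component unions equal the MRCA on every topology."""
        for n, catalog in catalogs.items():
            if n < 3:
                continue
            comp = min_clade_components([tu("A"), tu("B"), tu("C")])
            assert len(comp.components) == 3
            for tree in catalog.topologies:
                at = annotated(tree)
                ids = leaf_ids(at)
                expected = oracle_min_clade(
                    [at.tree.node(ids[l]) for l in "ABC"], at.tree)
                assert union_eval(comp, at) == {expected.node_id}, \
                    f"min ABC on {at.tree.source_newick}"

    def test_max_clade_ordered_pairs_exhaustive(self, small_catalogs):
        for catalog in small_catalogs.values():
            for tree in catalog.topologies:
                at = annotated(tree)
                ids = leaf_ids(at)
                for a, b in itertools.permutations(sorted(ids), 2):
                    comp = max_clade_components([tu(a)], [tu(b)])
                    expected = oracle_max_clade(
                        [at.tree.node(ids[a])], [at.tree.node(ids[b])], at.tree)
                    resolved = union_eval(comp, at)
                    if expected is None:
                        assert resolved == set()
                    else:
                        assert resolved == {expected.node_id}, \
                            f"max {a}/{b} on {at.tree.source_newick}"

    def test_specifier_permutation_invariance(self, small_catalogs):
        """Shuffling specifier order never changes the resolved node set."""
        for catalog in small_catalogs.values():
            for tree in catalog.topologies[:10]:
                at = annotated(tree)
                ids = leaf_ids(at)
                letters = sorted(ids)[:3]
                if len(letters) < 3:
                    continue
                baseline = None
                for perm in itertools.permutations(letters):
                    comp = min_clade_components([tu(l) for l in perm])
                    resolved = union_eval(comp, at)
                    if baseline is None:
                        baseline = resolved
                    assert resolved == baseline
                swapped = union_eval(
                    max_clade_components([tu(letters[0])],
                                         [tu(letters[2]), tu(letters[1])]), at)
                straight = union_eval(
                    max_clade_components([tu(letters[0])],
                                         [tu(letters[1]), tu(letters[2])]), at)
                assert swapped == straight
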