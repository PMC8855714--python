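"""The evaluator against a per-node brute-force oracle, the clade oracles,
and end-to-end phyloreference resolution."""

import itertools
import json

import pytest

from phyx import (
    And,
    ExcludesLineageTo,
    ExcludesTU,
    HasAncestor,
    HasChild,
    IncludesTU,
    Phyloreference,
    ResolutionStatus,
    TaxonomicUnit,
    annotate,
    build_name_index,
    evaluate,
    excludes_tu,
    includes_tu,
    load_phyx,
    match_tu,
    oracle_max_clade,
    oracle_min_clade,
    resolve_document,
    resolve_on_reference_tree,
    resolve_phyloref,
    write_newick,
)
from phyx.phyx_document import Phylogeny


def tu(letter):
    return TaxonomicUnit.from_name(letter)


def annotated_from(newick):
    return annotate(Phylogeny(newick=newick, id="#phylogeny0"))


def leaf_ids(at):
    return {node.label: node.node_id for node in at.tree.leaves()}


# ---------------------------------------------------------------------------
# Independent brute-force oracle: per-node truth evaluation straight from
# the relation definitions, sharing no code with the set-based evaluator.
# ---------------------------------------------------------------------------

def brute_force_satisfies(expr, node, at, parents):
    def represents(n, unit):
        return any(match_tu(unit, u) for u in at.represents.get(n.node_id, []))

    def subtree(n):
        yield n
        for child in n.children:
            yield from subtree(child)

    def sibling_lineage(n):
        parent = parents.get(n.node_id)
        if parent is None:
            return
        for child in parent.children:
            if child is not n:
                yield from subtree(child)

    def strict_ancestors(n):
        current = parents.get(n.node_id)
        while current is not None:
            yield current
            current = parents.get(current.node_id)

    if isinstance(expr, IncludesTU):
        return any(represents(m, expr.tu) for m in subtree(node))
    if isinstance(expr, ExcludesTU):
        return any(represents(m, expr.tu) for m in sibling_lineage(node))
    if isinstance(expr, ExcludesLineageTo):
        return any(brute_force_satisfies(expr.expr, m, at, parents)
                   for m in sibling_lineage(node))
    if isinstance(expr, HasChild):
        return any(brute_force_satisfies(expr.expr, c, at, parents)
                   for c in node.children)
    if isinstance(expr, HasAncestor):
        return any(brute_force_satisfies(expr.expr, m, at, parents)
                   for m in strict_ancestors(node))
    if isinstance(expr, And):
        return all(brute_force_satisfies(op, node, at, parents)
                   for op in expr.operands)
    raise TypeError(type(expr))


def brute_force_evaluate(expr, at):
    parents = {}
    for node in at.tree.nodes():
        for child in node.children:
            parents[child.node_id] = node
    return {n.node_id for n in at.tree.nodes()
            if brute_force_satisfies(expr, n, at, parents)}


def expression_zoo(letters):
    """A varied set of expressions over the available leaf letters."""
    a, b, c = letters[0], letters[1], letters[-1]
    return [
        IncludesTU(tu(a)),
        ExcludesTU(tu(c)),
        And([IncludesTU(tu(a)), ExcludesTU(tu(c))]),
        HasChild(And([IncludesTU(tu(a)), ExcludesTU(tu(b))])),
        ExcludesLineageTo(IncludesTU(tu(b))),
        HasAncestor(ExcludesTU(tu(c))),
        HasChild(ExcludesLineageTo(And([IncludesTU(tu(b)), ExcludesTU(tu(a))]))),
    ]


class TestEvaluator:
    def test_agrees_with_brute_force_exhaustively(self, small_catalogs):
        for n, catalog in small_catalogs.items():
            letters = "ABCDE"[:n]
            for tree in catalog.topologies:
                at = annotate(Phylogeny(newick=write_newick(tree)))
                for expr in expression_zoo(letters):
                    assert evaluate(expr, at) == brute_force_evaluate(expr, at), \
                        f"{expr!r} on {at.tree.source_newick}"

    def test_has_child_on_single_leaf_tree(self):
        at = annotated_from("A;")
        assert evaluate(HasChild(IncludesTU(tu("A"))), at) == set()

    def test_includes_excludes_node_level(self):
        at = annotated_from("((A,B)x,C);")
        nodes = {n.label: n for n in at.tree.nodes() if n.label}
        x = at.tree.node(at.tree.root.children[0].node_id)
        assert includes_tu(x, tu("A"), at)
        assert includes_tu(nodes["A"], tu("A"), at)  # the node itself counts
        assert not includes_tu(nodes["A"], tu("C"), at)
        assert excludes_tu(x, tu("C"), at)
        assert not excludes_tu(at.tree.root, tu("C"), at)

    def test_excludes_via_polytomy_sibling(self):
        at = annotated_from("(A,B,C);")
        a = next(n for n in at.tree.leaves() if n.label == "A")
        assert excludes_tu(a, tu("C"), at)


class TestCladeOracles:
    def test_min_is_mrca(self):
        at = annotated_from("(((A,B),C),D);")
        ids = leaf_ids(at)
        node = oracle_min_clade([at.tree.node(ids["A"]), at.tree.node(ids["B"])],
                                at.tree)
        assert {l.label for l in at.tree.node(node.node_id).walk() if l.is_leaf} == {"A", "B"}

    def test_max_walk_halts_immediately(self):
        at = annotated_from("((A,C),B);")
        ids = leaf_ids(at)
        node = oracle_max_clade([at.tree.node(ids["A"])],
                                [at.tree.node(ids["C"])], at.tree)
        assert node.node_id == ids["A"]

    def test_max_absent_when_external_below_mrca(self):
        at = annotated_from("((A,B),C);")
        ids = leaf_ids(at)
        assert oracle_max_clade(
            [at.tree.node(ids["A"]), at.tree.node(ids["C"])],
            [at.tree.node(ids["B"])], at.tree) is None

    def test_empty_internals_rejected(self):
        at = annotated_from("(A,B);")
        with pytest.raises(ValueError):
            oracle_min_clade([], at.tree)


class TestResolvePhyloref:
    def test_crocodylia_end_to_end(self, crocodylia_doc):
        results = resolve_document(crocodylia_doc)
        assert len(results) == 1
        result = results[0]
        assert result.status is ResolutionStatus.RESOLVED_UNIQUE
        assert result.resolved_labels == ["Alligatoroidea"]
        assert result.expectation_met is True
        # union invariant: resolved nodes equal the per-component union
        union = set()
        for nodes in result.per_component.values():
            union |= nodes
        assert union == result.resolved_nodes

    def test_unmatched_specifiers_unresolved(self):
        doc = load_phyx(json.dumps({
            "@context": "http://example.org/context.json",
            "phylogenies": [{"@id": "#phylogeny0", "newick": "(A,B);"}],
            "phylorefs": [{
                "phylorefType": "minimum-clade",
                "definition": "d",
                "internalSpecifiers": [
                    {"hasName": {"nameComplete": "Zzz zzz"}},
                    {"hasName": {"nameComplete": "Yyy yyy"}},
                ],
            }],
        }))
        result = resolve_document(doc)[0]
        assert result.status is ResolutionStatus.UNRESOLVED
        assert result.resolved_nodes == set()

    def test_apomorphy_unsupported_status(self):
        p = Phyloreference(definition="d", phyloref_type="apomorphy-based",
                           internal_specifiers=[tu("A")])
        result = resolve_phyloref(p, Phylogeny(newick="(A,B);", id="#p"))
        assert result.status is ResolutionStatus.UNSUPPORTED

    def test_min_clade_matches_oracle_on_all_topologies(self, catalogs):
        """End-to-end: the two-internal definition lands on the MRCA, n=2..6."""
        for catalog in catalogs.values():
            for tree in catalog.topologies:
                phylogeny = Phylogeny(newick=write_newick(tree), id="#p")
                at = annotate(phylogeny)
                ids = leaf_ids(at)
                p = Phyloreference(definition="d", phyloref_type="minimum-clade",
                                   internal_specifiers=[tu("A"), tu("B")])
                result = resolve_phyloref(p, phylogeny)
                expected = oracle_min_clade(
                    [at.tree.node(ids["A"]), at.tree.node(ids["B"])], at.tree)
                assert result.resolved_nodes == {expected.node_id}

    def test_max_clade_matches_oracle_on_all_topologies(self, catalogs):
        for n, catalog in catalogs.items():
            if n < 3:
                continue
            for tree in catalog.topologies:
                phylogeny = Phylogeny(newick=write_newick(tree), id="#p")
                at = annotate(phylogeny)
                ids = leaf_ids(at)
                p = Phyloreference(definition="d", phyloref_type="maximum-clade",
                                   internal_specifiers=[tu("A")],
                                   external_specifiers=[tu("C")])
                result = resolve_phyloref(p, phylogeny)
                expected = oracle_max_clade(
                    [at.tree.node(ids["A"])], [at.tree.node(ids["C"])], at.tree)
                assert result.resolved_nodes == {expected.node_id}


class TestReferenceTreeResolution:
    def test_min_clade_on_reference_tree(self):
        at = annotated_from("(((A,B),C),D);")
        ids = leaf_ids(at)
        p = Phyloreference(definition="d", phyloref_type="minimum-clade",
                           internal_specifiers=[tu("A"), tu("B")])
        node_id = resolve_on_reference_tree(p, at)
        expected = oracle_min_clade(
            [at.tree.node(ids["A"]), at.tree.node(ids["B"])], at.tree)
        assert node_id == expected.node_id

    def test_max_clade_returns_first_excluding_node(self):
        at = annotated_from("(((A,B),C),D);")
        p = Phyloreference(definition="d", phyloref_type="maximum-clade",
                           internal_specifiers=[tu("A")],
                           external_specifiers=[tu("D")])
        node_id = resolve_on_reference_tree(p, at)
        leaves = {l.label for l in at.tree.node(node_id).walk() if l.is_leaf}
        assert leaves == {"A", "B", "C"}

    def test_unknown_name_skips(self):
        at = annotated_from("(((A,B),C),D);")
        p = Phyloreference(definition="d", phyloref_type="minimum-clade",
                           internal_specifiers=[tu("A"),
                                                TaxonomicUnit.from_name("Zzz zzz")])
        assert resolve_on_reference_tree(p, at) is None

    def test_agrees_with_min_oracle_exhaustively(self, small_catalogs):
        for catalog in small_catalogs.values():
            for tree in catalog.topologies:
                at = annotate(Phylogeny(newick=write_newick(tree)))
                ids = leaf_ids(at)
                index = build_name_index(at)
                for a, b in itertools.combinations(sorted(ids), 2):
                    p = Phyloreference(definition="d",
                                       phyloref_type="minimum-clade",
                                       internal_specifiers=[tu(a), tu(b)])
                    expected = oracle_min_clade(
                        [at.tree.node(ids[a]), at.tree.node(ids[b])], at.tree)
                    assert resolve_on_reference_tree(p, at, index) == expected.node_id

    def test_internal_labels_indexed_on_request(self):
        at = annotated_from("((A,B)Inner,C);")
        default_index = build_name_index(at)
        full_index = build_name_index(at, leaves_only=False)
        assert "Inner" not in default_index
        assert "Inner" in full_index
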