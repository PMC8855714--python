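"""Evaluate clade-definition expressions directly against trees.

The ontology pipeline delegates resolution to an OWL reasoner; this
module is the self-contained replacement: it annotates a phylogeny's
nodes with the taxonomic units they represent, evaluates node-class
expressions under the documented semantics, and provides two independent
clade oracles (MRCA for minimum clades, the rootward walk for maximum
clades) plus the offline form of the two-step reference-tree algorithm
used for resolving names against a large synthesis tree.

Semantics (all purely topological):

* a node *includes* a TU if it, or a strict descendant, represents a
  matching unit;
* a node *excludes* a TU if a sibling, or a descendant of a sibling,
  represents a matching unit;
* ``excludes_lineage_to(E)`` holds where some node satisfying *E* is a
  sibling or a descendant of a sibling;
* ``has_Child`` looks one step down, ``has_Ancestor`` any number of
  steps up (strict);
* intersections intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Dict, FrozenSet, List, Optional, Set

from .clade_expressions import (
    And,
    ExcludesLineageTo,
    ExcludesTU,
    HasAncestor,
    HasChild,
    IncludesTU,
    NodeClassExpression,
    UnsupportedPhylorefType,
    phyloref_to_components,
)
from .taxonomic_units import (
    TaxonConcept,
    TaxonNameParseError,
    TaxonomicUnit,
    match_tu,
    parse_taxon_name,
)
from .tree_model import RootedTree, TreeNode, mrca

if TYPE_CHECKING:  # pragma: no cover
    from .phyx_document import Phylogeny, Phyloreference, PhyxDocument

__all__ = [
    "AnnotatedTree",
    "ResolutionStatus",
    "ResolutionResult",
    "annotate",
    "node_taxonomic_units",
    "includes_tu",
    "excludes_tu",
    "evaluate",
    "oracle_min_clade",
    "oracle_max_clade",
    "resolve_phyloref",
    "resolve_document",
    "build_name_index",
    "resolve_on_reference_tree",
]


def node_taxonomic_units(
    phylogeny: "Phylogeny", node: TreeNode, default_code: Optional[str] = None
) -> List[TaxonomicUnit]:
    """The TUs one node represents.

    Every labeled node contributes a taxon-concept TU parsed from its
    label (labels that do not read as scientific names, such as purely
    structural labels, contribute nothing); ``additionalNodeProperties``
    entries keyed by the label add further units.
    """
    tus: List[TaxonomicUnit] = []
    if node.label:
        try:
            tus.append(TaxonomicUnit(taxon_concept=TaxonConcept(
                hasName=parse_taxon_name(node.label, default_code))))
        except TaxonNameParseError:
            pass
        extra = phylogeny.additional_node_properties.get(node.label, {})
        for raw in extra.get("representsTaxonomicUnits", []):
            try:
                tus.append(TaxonomicUnit.from_jsonld(raw, default_code))
            except (ValueError, TypeError):
                pass
    return tus


@dataclass
class AnnotatedTree:
    """A rooted tree plus the node → taxonomic-unit association."""

    tree: RootedTree
    represents: Dict[str, List[TaxonomicUnit]] = field(default_factory=dict)
    phylogeny_id: Optional[str] = None

    def matching_nodes(self, tu: TaxonomicUnit) -> Set[str]:
        """Node ids directly representing a unit matching ``tu``."""
        return {
            node_id
            for node_id, units in self.represents.items()
            if any(match_tu(tu, unit) for unit in units)
        }

    def label_of(self, node_id: str) -> Optional[str]:
        return self.tree.node(node_id).label


def annotate(phylogeny: "Phylogeny", default_code: Optional[str] = None) -> AnnotatedTree:
    """Parse a phylogeny's Newick string and attach TUs to its nodes."""
    tree = phylogeny.tree()
    represents: Dict[str, List[TaxonomicUnit]] = {}
    for node in tree.nodes():
        tus = node_taxonomic_units(phylogeny, node, default_code)
        if tus:
            represents[node.node_id] = tus
    return AnnotatedTree(tree=tree, represents=represents, phylogeny_id=phylogeny.id)


# ---------------------------------------------------------------------------
# Structural caches
# ---------------------------------------------------------------------------

class _Relations:
    """Precomputed descendant-or-self and sibling-lineage sets."""

    def __init__(self, tree: RootedTree):
        self.tree = tree
        self.desc_or_self: Dict[str, FrozenSet[str]] = {}
        self.sibling_lineage: Dict[str, FrozenSet[str]] = {}
        self.children: Dict[str, List[str]] = {}
        self.ancestors: Dict[str, FrozenSet[str]] = {}
        self._fill(tree.root, [])

    def _fill(self, node: TreeNode, lineage: List[str]) -> None:
        self.ancestors[node.node_id] = frozenset(lineage)
        self.children[node.node_id] = [c.node_id for c in node.children]
        lineage.append(node.node_id)
        acc: Set[str] = {node.node_id}
        for child in node.children:
            self._fill(child, lineage)
            acc |= self.desc_or_self[child.node_id]
        lineage.pop()
        self.desc_or_self[node.node_id] = frozenset(acc)
        for child in node.children:
            sib: Set[str] = set()
            for other in node.children:
                if other is not child:
                    sib |= self.desc_or_self[other.node_id]
            self.sibling_lineage[child.node_id] = frozenset(sib)
        if node is self.tree.root:
            self.sibling_lineage[node.node_id] = frozenset()


# ---------------------------------------------------------------------------
# Node-level relations and expression evaluation
# ---------------------------------------------------------------------------

def includes_tu(node: TreeNode, tu: TaxonomicUnit, at: AnnotatedTree) -> bool:
    """The node, or a strict descendant, represents a matching unit."""
    at.tree._require(node)
    matching = at.matching_nodes(tu)
    return any(n.node_id in matching for n in node.walk())


def excludes_tu(node: TreeNode, tu: TaxonomicUnit, at: AnnotatedTree) -> bool:
    """A sibling, or a descendant of a sibling, represents a matching unit."""
    at.tree._require(node)
    relations = _Relations(at.tree)
    matching = at.matching_nodes(tu)
    return bool(relations.sibling_lineage[node.node_id] & matching)


def evaluate(expr: NodeClassExpression, at: AnnotatedTree) -> Set[str]:
    """The set of node ids satisfying ``expr`` on the annotated tree."""
    relations = _Relations(at.tree)
    return set(_evaluate(expr, at, relations))


def _evaluate(expr: NodeClassExpression, at: AnnotatedTree, rel: _Relations) -> FrozenSet[str]:
    all_ids = rel.desc_or_self[at.tree.root.node_id]
    if isinstance(expr, IncludesTU):
        matching = at.matching_nodes(expr.tu)
        return frozenset(n for n in all_ids if rel.desc_or_self[n] & matching)
    if isinstance(expr, ExcludesTU):
        matching = at.matching_nodes(expr.tu)
        return frozenset(n for n in all_ids if rel.sibling_lineage[n] & matching)
    if isinstance(expr, ExcludesLineageTo):
        sat = _evaluate(expr.expr, at, rel)
        return frozenset(n for n in all_ids if rel.sibling_lineage[n] & sat)
    if isinstance(expr, HasChild):
        sat = _evaluate(expr.expr, at, rel)
        return frozenset(n for n in all_ids if any(c in sat for c in rel.children[n]))
    if isinstance(expr, HasAncestor):
        sat = _evaluate(expr.expr, at, rel)
        return frozenset(n for n in all_ids if rel.ancestors[n] & sat)
    if isinstance(expr, And):
        result = all_ids
        for op in expr.operands:
            result = result & _evaluate(op, at, rel)
        return frozenset(result)
    raise TypeError(f"unknown expression type {type(expr).__name__}")


# ---------------------------------------------------------------------------
# Clade oracles
# ---------------------------------------------------------------------------

def oracle_min_clade(internal_nodes: List[TreeNode], tree: RootedTree) -> TreeNode:
    """The MRCA of the internal nodes (minimum-clade semantics)."""
    if not internal_nodes:
        raise ValueError("minimum clade of an empty specifier set is undefined")
    return mrca(internal_nodes, tree)


def oracle_max_clade(
    internal_nodes: List[TreeNode],
    external_nodes: List[TreeNode],
    tree: RootedTree,
) -> Optional[TreeNode]:
    """The largest external-free clade containing the internals.

    Starting at the internals' MRCA, walk rootward while the subtree
    stays free of every external node; the last such node is the maximum
    clade.  Returns ``None`` when an external already descends from the
    MRCA itself (the requested clade does not exist on this tree).
    """
    if not internal_nodes:
        raise ValueError("maximum clade of an empty internal set is undefined")
    current = mrca(internal_nodes, tree)
    external_ids = {n.node_id for n in external_nodes}

    def subtree_hits(node: TreeNode) -> bool:
        return any(d.node_id in external_ids for d in node.walk())

    if subtree_hits(current):
        return None
    while True:
        parent = tree.parent(current)
        if parent is None or subtree_hits(parent):
            return current
        current = parent


# ---------------------------------------------------------------------------
# End-to-end resolution
# ---------------------------------------------------------------------------

class ResolutionStatus(str, Enum):
    RESOLVED_UNIQUE = "resolved-unique"
    RESOLVED_MULTIPLE = "resolved-multiple"
    UNRESOLVED = "unresolved"
    UNSUPPORTED = "unsupported"


@dataclass
class ResolutionResult:
    """Outcome of resolving one phyloreference on one phylogeny."""

    phyloref_id: str
    phylogeny_id: str
    resolved_nodes: Set[str] = field(default_factory=set)
    per_component: Dict[int, Set[str]] = field(default_factory=dict)
    status: ResolutionStatus = ResolutionStatus.UNRESOLVED
    resolved_labels: List[str] = field(default_factory=list)
    expected_label: Optional[str] = None
    expectation_met: Optional[bool] = None


def resolve_phyloref(
    p: "Phyloreference",
    phylogeny: "Phylogeny",
    doc: Optional["PhyxDocument"] = None,
) -> ResolutionResult:
    """Generate components, evaluate each, union, compare to expectation.

    The per-component node sets are retained so the behavior of each
    emitted expression remains observable; ``resolved_nodes`` is always
    their union.
    """
    default_code = doc.default_nomenclatural_code if doc is not None else None
    at = annotate(phylogeny, default_code)
    result = ResolutionResult(
        phyloref_id=p.id or "", phylogeny_id=phylogeny.id or "")
    expected = p.expected_resolution.get(phylogeny.id) if phylogeny.id else None
    if expected is not None:
        result.expected_label = expected.node_label
    try:
        component_set = phyloref_to_components(p)
    except UnsupportedPhylorefType:
        result.status = ResolutionStatus.UNSUPPORTED
        return result
    relations = _Relations(at.tree)
    for j, expr in enumerate(component_set.components):
        sat = set(_evaluate(expr, at, relations))
        result.per_component[j] = sat
        result.resolved_nodes |= sat
    count = len(result.resolved_nodes)
    result.status = (
        ResolutionStatus.UNRESOLVED if count == 0
        else ResolutionStatus.RESOLVED_UNIQUE if count == 1
        else ResolutionStatus.RESOLVED_MULTIPLE
    )
    result.resolved_labels = sorted(
        at.label_of(n) or n for n in result.resolved_nodes
    )
    if result.expected_label is not None:
        result.expectation_met = (
            count == 1 and result.resolved_labels == [result.expected_label]
        )
    return result


def resolve_document(doc: "PhyxDocument") -> List[ResolutionResult]:
    """Resolve every phyloreference against every phylogeny in a document."""
    return [
        resolve_phyloref(p, phylogeny, doc)
        for p in doc.phylorefs
        for phylogeny in doc.phylogenies
    ]


# ---------------------------------------------------------------------------
# Reference-tree (two-step) resolution
# ---------------------------------------------------------------------------

def build_name_index(at: AnnotatedTree, leaves_only: bool = True) -> Dict[str, str]:
    """Map ``nameComplete`` strings to node ids for name translation.

    By default only leaf labels are indexed, mirroring how taxonomic
    names are translated against a synthesis tree; pass
    ``leaves_only=False`` to index internal labels too.
    """
    index: Dict[str, str] = {}
    for node in at.tree.nodes():
        if leaves_only and not node.is_leaf:
            continue
        for tu in at.represents.get(node.node_id, []):
            name = tu.name_complete
            if name and name not in index:
                index[name] = node.node_id
    return index


def resolve_on_reference_tree(
    p: "Phyloreference",
    reference: AnnotatedTree,
    name_index: Optional[Dict[str, str]] = None,
) -> Optional[str]:
    """The two-step name-then-MRCA algorithm against a loaded tree.

    Step 1 translates each specifier's taxonomic name through the index;
    if any name is missing the phyloreference is skipped (``None``).
    Step 2 computes, for a minimum clade, the internals' MRCA (a
    one-node list), and for a maximum clade the list from the earliest
    external-excluding ancestor down to that MRCA, returning its first
    node.  Only name-bearing specifiers are supported.
    """
    if name_index is None:
        name_index = build_name_index(reference)
    tree = reference.tree

    def translate(tus: List[TaxonomicUnit]) -> Optional[List[TreeNode]]:
        nodes = []
        for tu in tus:
            name = tu.name_complete
            if name is None or name not in name_index:
                return None
            nodes.append(tree.node(name_index[name]))
        return nodes

    internals = translate(p.internal_specifiers)
    if internals is None or not internals:
        return None
    if p.phyloref_type == "maximum-clade" or (
        p.phyloref_type == "minimum-clade" and len(internals) == 1 and p.external_specifiers
    ):
        externals = translate(p.external_specifiers)
        if externals is None:
            return None
        top = oracle_max_clade(internals, externals, tree)
        return top.node_id if top is not None else None
    if p.phyloref_type == "minimum-clade":
        return oracle_min_clade(internals, tree).node_id
    return None  # apomorphy-based definitions are skipped
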