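"""Exhaustive topology enumeration and the two-phyloreference sweep.

To show that clade-definition resolution does not depend on any
particular branching structure, every rooted tree on *n* labeled leaves
(2 ≤ n ≤ 6, internal out-degrees ≥ 2, polytomies included) is
enumerated, every node is labeled by a scheme that encodes its
descendant and sibling leaves, and two test definitions — the minimum
clade of leaves A and B, and the maximum clade including A but
excluding C — are resolved on every topology and compared against the
node the labeling scheme predicts.

The totals are 1, 4, 26, 236 and 2,752 topologies for n = 2..6, of
which 1, 3, 15, 105 and 945 are strictly bifurcating (the
(2n−3)!! double-factorial series).

Labeling scheme: a node whose descendant leaves are {A,B} and whose
sibling subtrees hold {C,D} is labeled ``NAB_CD`` — "N", the descendant
leaf letters in alphabetical order, an underscore, then the letters of
all leaves under (or equal to) any sibling.  The root of a five-leaf
tree is therefore always ``NABCDE_``.  The expected minimum clade is
the node with the fewest-leaf label starting ``NAB``; the expected
maximum clade is the fewest-leaf label matching ``NA.*_.*C.*`` ("A
inside, C excluded through a sibling").  "Fewest-leaf" orders labels by
the number of letters before the underscore, which is what "shortest
label" means for this scheme; string ties between distinct nodes cannot
occur because two clades sharing leaf A are nested.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .phyx_document import (
    ExpectedResolution,
    Phylogeny,
    Phyloreference,
    PhyxDocument,
)
from .resolution import ResolutionStatus, resolve_phyloref
from .taxonomic_units import TaxonomicUnit
from .tree_model import RootedTree, TreeNode, write_newick
from . import terms

__all__ = [
    "TopologyCatalog",
    "SweepRecord",
    "SweepReport",
    "enumerate_topologies",
    "label_scheme",
    "expected_nodes",
    "build_sweep_document",
    "run_sweep",
]

MIN_LEAVES, MAX_LEAVES = 1, 7

# canonical nested-tuple form: leaves are their labels, clades are sorted
# tuples of child canonical forms
_Canon = Tuple


def _canon(node: TreeNode) -> _Canon:
    if node.is_leaf:
        return node.label
    return tuple(sorted((_canon(c) for c in node.children), key=repr))


def _from_canon(canon: _Canon) -> TreeNode:
    if isinstance(canon, str):
        return TreeNode(label=canon)
    return TreeNode(children=[_from_canon(c) for c in canon])


def _insertions(canon: _Canon, leaf: str) -> List[_Canon]:
    """All trees obtained by adding ``leaf`` somewhere in ``canon``.

    The new leaf can split any edge (including the root edge, creating a
    new root) or join any existing internal node as an extra child; the
    two moves together generate every topology on k+1 leaves from the
    catalog on k leaves.
    """
    out: List[_Canon] = [tuple(sorted([canon, leaf], key=repr))]  # split root edge
    if not isinstance(canon, str):
        out.append(tuple(sorted(list(canon) + [leaf], key=repr)))  # widen this node
        for i, child in enumerate(canon):
            for replacement in _insertions(child, leaf):
                rebuilt = list(canon)
                rebuilt[i] = replacement
                out.append(tuple(sorted(rebuilt, key=repr)))
    return out


def _is_bifurcating(canon: _Canon) -> bool:
    if isinstance(canon, str):
        return True
    return len(canon) == 2 and all(_is_bifurcating(c) for c in canon)


@dataclass
class TopologyCatalog:
    """Every rooted labeled topology on the first ``n_leaves`` letters."""

    n_leaves: int
    topologies: List[RootedTree]
    counts: Dict[str, int]


def enumerate_topologies(n: int) -> TopologyCatalog:
    """Enumerate all rooted trees on ``n`` labeled leaves, exactly once each.

    Internal nodes have out-degree ≥ 2, so both bifurcating trees and
    polytomies appear; no two results are isomorphic as labeled rooted
    trees (enumeration deduplicates on a canonical sorted-tuple form).
    """
    if not (MIN_LEAVES <= n <= MAX_LEAVES):
        raise ValueError(f"leaf count must be between {MIN_LEAVES} and {MAX_LEAVES}, got {n}")
    letters = string.ascii_uppercase[:n]
    forms: List[_Canon] = [letters[0]]
    for leaf in letters[1:]:
        seen = set()
        next_forms: List[_Canon] = []
        for form in forms:
            for candidate in _insertions(form, leaf):
                if candidate not in seen:
                    seen.add(candidate)
                    next_forms.append(candidate)
        forms = next_forms
    trees = [RootedTree(_from_canon(f)) for f in forms]
    bifurcating = sum(1 for f in forms if _is_bifurcating(f))
    counts = {
        "total": len(forms),
        "bifurcating": bifurcating,
        "multifurcating": len(forms) - bifurcating,
    }
    return TopologyCatalog(n_leaves=n, topologies=trees, counts=counts)


# ---------------------------------------------------------------------------
# Node labeling scheme
# ---------------------------------------------------------------------------

def label_scheme(tree: RootedTree) -> RootedTree:
    """Return a copy of ``tree`` with every node carrying its scheme label.

    Leaves must bear distinct single-letter labels.  Each node is
    relabeled ``"N" + <sorted descendant-or-self leaf letters> + "_" +
    <sorted letters of leaves under or equal to any sibling>``; the
    underscore is emitted even for the root, whose sibling part is empty.
    """
    letters = [leaf.label for leaf in tree.leaves()]
    if any(l is None or len(l) != 1 for l in letters):
        raise ValueError("scheme labeling requires single-letter leaf labels")
    if len(set(letters)) != len(letters):
        raise ValueError(f"duplicate leaf letters: {sorted(letters)}")

    def clone(node: TreeNode) -> Tuple[TreeNode, str]:
        """Copy the subtree, returning (copy, its sorted descendant letters)."""
        if node.is_leaf:
            return TreeNode(label=node.label), node.label
        pairs = [clone(c) for c in node.children]
        copy = TreeNode(children=[p[0] for p in pairs])
        copy._letters_per_child = [p[1] for p in pairs]  # type: ignore[attr-defined]
        return copy, "".join(sorted("".join(p[1] for p in pairs)))

    root_copy, _ = clone(tree.root)

    def assign(node: TreeNode, sibling_letters: str) -> str:
        if node.is_leaf:
            own = node.label
        else:
            own = "".join(sorted("".join(node._letters_per_child)))  # type: ignore[attr-defined]
        node.label = f"N{own}_{''.join(sorted(sibling_letters))}"
        if not node.is_leaf:
            per_child = node._letters_per_child  # type: ignore[attr-defined]
            for i, child in enumerate(node.children):
                sibs = "".join(per_child[j] for j in range(len(per_child)) if j != i)
                assign(child, sibs)
            del node._letters_per_child  # type: ignore[attr-defined]
        return own

    assign(root_copy, "")
    return RootedTree(root_copy)


_MAX_PATTERN = re.compile(r"NA.*_.*C.*")


def _scheme_parts(label: str) -> Tuple[str, str]:
    head, _, tail = label.partition("_")
    return head[1:], tail  # strip leading "N"


def expected_nodes(labeled: RootedTree) -> Dict[str, Optional[str]]:
    """Where the two test phyloreferences must resolve on a labeled tree.

    ``min``: fewest-leaf label starting ``NAB`` (MRCA of A and B);
    ``max``: fewest-leaf label matching ``NA.*_.*C.*`` (largest clade
    with A inside and C excluded through a sibling), or ``None`` when no
    label matches (e.g. trees without a C leaf).
    """
    labels = [n.label for n in labeled.nodes() if n.label]

    def fewest(cands: List[str]) -> Optional[str]:
        if not cands:
            return None
        return min(cands, key=lambda l: (len(_scheme_parts(l)[0]), l))

    return {
        "min": fewest([l for l in labels if l.startswith("NAB")]),
        "max": fewest([l for l in labels if _MAX_PATTERN.match(l)]),
    }


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

def _letter_tu(letter: str) -> TaxonomicUnit:
    return TaxonomicUnit.from_name(letter)


def build_sweep_document(labeled: RootedTree) -> PhyxDocument:
    """Embed one scheme-labeled topology plus the two test phyloreferences.

    Leaves are associated with their single-letter taxonomic units via
    ``additionalNodeProperties`` (the node labels themselves are scheme
    labels, which are not taxon names); the phyloreferences are named
    after the labels of the nodes where they are expected to resolve.
    """
    newick = write_newick(labeled)
    expected = expected_nodes(labeled)
    props: Dict[str, Dict] = {}
    for leaf in labeled.leaves():
        letter = _scheme_parts(leaf.label)[0]
        props[leaf.label] = {
            "representsTaxonomicUnits": [{
                "@type": terms.TC_TAXON_CONCEPT,
                "hasName": {"@type": terms.TN_TAXON_NAME, "nameComplete": letter},
            }]
        }
    phylogeny = Phylogeny(newick=newick, id="#phylogeny0",
                          additional_node_properties=props)
    minimum = Phyloreference(
        id="#phyloref-min",
        label=expected["min"],
        phyloref_type="minimum-clade",
        definition="The smallest clade containing A and B.",
        internal_specifiers=[_letter_tu("A"), _letter_tu("B")],
        expected_resolution=(
            {"#phylogeny0": ExpectedResolution(node_label=expected["min"])}
            if expected["min"] else {}
        ),
    )
    maximum = Phyloreference(
        id="#phyloref-max",
        label=expected["max"],
        phyloref_type="maximum-clade",
        definition="The largest clade containing A but not C.",
        internal_specifiers=[_letter_tu("A")],
        external_specifiers=[_letter_tu("C")],
        expected_resolution=(
            {"#phylogeny0": ExpectedResolution(node_label=expected["max"])}
            if expected["max"] else {}
        ),
    )
    return PhyxDocument(
        context=terms.PHYX_CONTEXT,
        phylogenies=[phylogeny],
        phylorefs=[minimum, maximum],
    )


@dataclass
class SweepRecord:
    newick: str
    expected_min: Optional[str]
    resolved_min: List[str]
    expected_max: Optional[str]
    resolved_max: List[str]
    min_pass: Optional[bool]
    max_pass: Optional[bool]


@dataclass
class SweepReport:
    """Per-topology outcomes plus the aggregate pass fraction.

    The fraction counts only (topology, phyloreference) pairs whose
    expected node exists; a definition whose clade cannot exist on a
    topology is additionally required to come back unresolved there.
    """

    n_leaves: int
    counts: Dict[str, int]
    records: List[SweepRecord] = field(default_factory=list)

    @property
    def checked(self) -> int:
        return sum(r.min_pass is not None for r in self.records) + \
            sum(r.max_pass is not None for r in self.records)

    @property
    def passed(self) -> int:
        return sum(bool(r.min_pass) for r in self.records) + \
            sum(bool(r.max_pass) for r in self.records)

    @property
    def pass_fraction(self) -> float:
        return self.passed / self.checked if self.checked else 1.0


def run_sweep(n: int) -> SweepReport:
    """Resolve the two test phyloreferences on every topology with ``n`` leaves."""
    if not (2 <= n <= 6):
        raise ValueError(f"sweep is defined for 2..6 leaves, got {n}")
    catalog = enumerate_topologies(n)
    report = SweepReport(n_leaves=n, counts=dict(catalog.counts))
    for tree in catalog.topologies:
        labeled = label_scheme(tree)
        doc = build_sweep_document(labeled)
        phylogeny = doc.phylogenies[0]
        expected = expected_nodes(labeled)
        record = SweepRecord(
            newick=phylogeny.newick,
            expected_min=expected["min"], resolved_min=[],
            expected_max=expected["max"], resolved_max=[],
            min_pass=None, max_pass=None,
        )
        for phyloref, which in ((doc.phylorefs[0], "min"), (doc.phylorefs[1], "max")):
            result = resolve_phyloref(phyloref, phylogeny, doc)
            labels = result.resolved_labels
            setattr(record, f"resolved_{which}", labels)
            want = expected[which]
            if want is not None:
                setattr(record, f"{which}_pass", labels == [want])
            elif result.status is not ResolutionStatus.UNRESOLVED:
                # no expected node: the definition must not resolve at all
                setattr(record, f"{which}_pass", False)
        report.records.append(record)
    return report
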