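"""Generate node-class expressions from a clade definition's specifiers.

A phyloreference resolves to the tree node(s) satisfying a logical
expression built from a small vocabulary of node-level relations:

* ``includes_TU(t)`` — the node, or a descendant, represents taxonomic
  unit *t* (so it holds on the whole ancestor lineage above *t*);
* ``excludes_TU(t)`` — a sibling of the node, or a descendant of a
  sibling, represents *t* (the lineage through the node excludes *t*);
* ``excludes_lineage_to(E)`` — some node satisfying *E* is a sibling, or
  a descendant of a sibling;
* ``has_Child(E)`` / ``has_Ancestor(E)`` — structural steps;
* intersection.

Disjunction is deliberately absent: it falls outside the OWL2 EL profile
targeted by the ontology output, so a definition needing alternatives is
emitted as several *component* expressions, each a separate subclass, and
a node resolving any component resolves the phyloreference.

The two-specifier building block — exactly the node whose child lineage
includes one specifier while a sibling lineage leads to the other — is

    has_Child some (includes_TU some i  and  excludes_TU some j)

which holds at precisely the most recent common ancestor of *i* and *j*
on any rooted tree, polytomies included.  Minimum-clade definitions with
*n* internal specifiers emit one component per unordered specifier pair
(n(n−1)/2 components): the pair's MRCA expression conjoined with
``includes_TU`` for every remaining internal.  Since the MRCA of a set is
always the MRCA of two of its members lying in different child subtrees,
the union of the components is exactly the MRCA of all internals (see the
methods note for the argument).  Maximum-clade definitions emit one
component per external specifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import TYPE_CHECKING, List, Sequence, Tuple

from .taxonomic_units import TaxonomicUnit

if TYPE_CHECKING:  # pragma: no cover
    from .phyx_document import Phyloreference

__all__ = [
    "NodeClassExpression",
    "IncludesTU",
    "ExcludesTU",
    "ExcludesLineageTo",
    "HasChild",
    "HasAncestor",
    "And",
    "ComponentSet",
    "SpecifierArityError",
    "UnsupportedPhylorefType",
    "expr_one_internal_one_external",
    "expr_two_internals",
    "min_clade_components",
    "max_clade_components",
    "phyloref_to_components",
]


class SpecifierArityError(ValueError):
    """The specifier counts do not fit the requested clade-definition type."""


class UnsupportedPhylorefType(ValueError):
    """No expression can be generated for this clade-definition type."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class NodeClassExpression:
    """Base class; subclasses form a small immutable AST."""

    def key(self) -> tuple:
        """Canonical, order-insensitive form used for dedup and hashing."""
        raise NotImplementedError

    def __eq__(self, other) -> bool:
        return isinstance(other, NodeClassExpression) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


def _tu_key(tu: TaxonomicUnit) -> tuple:
    return (tu.id, tu.name_complete, tu.specimen)


@dataclass(frozen=True, eq=False)
class IncludesTU(NodeClassExpression):
    tu: TaxonomicUnit

    def key(self):
        return ("includes_TU", _tu_key(self.tu))

    def __repr__(self):
        return f"includes_TU({self.tu.describe()})"


@dataclass(frozen=True, eq=False)
class ExcludesTU(NodeClassExpression):
    tu: TaxonomicUnit

    def key(self):
        return ("excludes_TU", _tu_key(self.tu))

    def __repr__(self):
        return f"excludes_TU({self.tu.describe()})"


@dataclass(frozen=True, eq=False)
class ExcludesLineageTo(NodeClassExpression):
    expr: NodeClassExpression

    def key(self):
        return ("excludes_lineage_to", self.expr.key())

    def __repr__(self):
        return f"excludes_lineage_to({self.expr!r})"


@dataclass(frozen=True, eq=False)
class HasChild(NodeClassExpression):
    expr: NodeClassExpression

    def key(self):
        return ("has_Child", self.expr.key())

    def __repr__(self):
        return f"has_Child({self.expr!r})"


@dataclass(frozen=True, eq=False)
class HasAncestor(NodeClassExpression):
    expr: NodeClassExpression

    def key(self):
        return ("has_Ancestor", self.expr.key())

    def __repr__(self):
        return f"has_Ancestor({self.expr!r})"


@dataclass(frozen=True, eq=False)
class And(NodeClassExpression):
    operands: Tuple[NodeClassExpression, ...]

    def __init__(self, operands: Sequence[NodeClassExpression]):
        operands = tuple(operands)
        if not operands:
            raise ValueError("intersection of zero expressions")
        object.__setattr__(self, "operands", operands)

    def key(self):
        return ("and", tuple(sorted((op.key() for op in self.operands), key=repr)))

    def __repr__(self):
        return "(" + " and ".join(repr(op) for op in self.operands) + ")"


def _and(operands: Sequence[NodeClassExpression]) -> NodeClassExpression:
    """Intersection, collapsing the single-operand case."""
    return operands[0] if len(operands) == 1 else And(operands)


@dataclass(frozen=True)
class ComponentSet:
    """The component expressions of one phyloreference.

    Each component becomes a separate component (sub)class in the ontology
    output; the phyloreference resolves to the union of the nodes its
    components resolve to.
    """

    phyloref_id: str
    components: Tuple[NodeClassExpression, ...] = field(default_factory=tuple)


def _dedup(exprs: Sequence[NodeClassExpression]) -> Tuple[NodeClassExpression, ...]:
    seen = set()
    out: List[NodeClassExpression] = []
    for e in exprs:
        k = e.key()
        if k not in seen:
            seen.add(k)
            out.append(e)
    return tuple(out)


def _specifier_sort_key(tu: TaxonomicUnit) -> tuple:
    return (tu.name_complete or "", tu.id or "", repr(tu.specimen))


# ---------------------------------------------------------------------------
# Expression families
# ---------------------------------------------------------------------------

def expr_one_internal_one_external(i: TaxonomicUnit, e: TaxonomicUnit) -> NodeClassExpression:
    """``includes_TU some i and excludes_TU some e``.

    Holds at every node on the lineage from *i* up to (and including) the
    last ancestor whose parent also covers *e* — evaluated on a tree, the
    largest such clade is the topmost satisfied node; the expression
    itself is satisfied exactly at the maximal *e*-free clade containing
    *i* (its parent must lead to *e* through a sibling).
    """
    return And([IncludesTU(i), ExcludesTU(e)])


def expr_two_internals(i1: TaxonomicUnit, i2: TaxonomicUnit) -> NodeClassExpression:
    """``has_Child some (includes_TU some i1 and excludes_TU some i2)``.

    Satisfied at exactly the MRCA of the two specifiers: the child lineage
    leads to *i1* while a sibling lineage leads to *i2*.  By sibling
    symmetry the specifier order is immaterial to the resolved node set.
    """
    return HasChild(And([IncludesTU(i1), ExcludesTU(i2)]))


def min_clade_components(internals: Sequence[TaxonomicUnit], phyloref_id: str = "") -> ComponentSet:
    """Components for a minimum-clade (MRCA) definition.

    One component per unordered pair of internal specifiers, i.e.
    n(n−1)/2 components: the pair's two-specifier MRCA expression
    conjoined with ``includes_TU`` for every other internal.  A node
    satisfies such a component only if it is the MRCA of the pair *and*
    covers all internals, which pins it to the MRCA of the whole set;
    some pair always straddles that node's child subtrees, so the union
    of components is exactly the full MRCA on every topology.
    """
    internals = list(internals)
    if len(internals) < 2:
        raise SpecifierArityError(
            f"a minimum-clade definition needs at least 2 internal specifiers, got {len(internals)}"
        )
    ordered = sorted(internals, key=_specifier_sort_key)
    components: List[NodeClassExpression] = []
    for i1, i2 in combinations(ordered, 2):
        others = [t for t in ordered if t is not i1 and t is not i2]
        pair_expr = expr_two_internals(i1, i2)
        components.append(_and([pair_expr] + [IncludesTU(t) for t in others]))
    return ComponentSet(phyloref_id=phyloref_id, components=_dedup(components))


def max_clade_components(
    internals: Sequence[TaxonomicUnit],
    externals: Sequence[TaxonomicUnit],
    phyloref_id: str = "",
) -> ComponentSet:
    """Components for a maximum-clade definition.

    One component per external specifier *e*: the intersection of
    ``includes_TU`` over all internals, ``excludes_TU some e``, and, for
    every other external *e'*, ``has_Ancestor some (excludes_TU some e')``.
    With a single external this is exact on every topology; with several
    externals branching off at the same split the union can be empty, in
    which case resolution reports the definition as unresolved rather
    than patching the construction.
    """
    internals, externals = list(internals), list(externals)
    if not internals or not externals:
        raise SpecifierArityError(
            "a maximum-clade definition needs at least 1 internal and 1 external specifier "
            f"(got {len(internals)} internal, {len(externals)} external)"
        )
    internals = sorted(internals, key=_specifier_sort_key)
    externals = sorted(externals, key=_specifier_sort_key)
    components: List[NodeClassExpression] = []
    for selected in externals:
        operands: List[NodeClassExpression] = [IncludesTU(i) for i in internals]
        operands.append(ExcludesTU(selected))
        for other in externals:
            if other is not selected:
                operands.append(HasAncestor(ExcludesTU(other)))
        components.append(_and(operands))
    return ComponentSet(phyloref_id=phyloref_id, components=_dedup(components))


def phyloref_to_components(p: "Phyloreference") -> ComponentSet:
    """Dispatch a phyloreference to its expression family.

    Minimum-clade definitions with one internal and at least one external
    specifier fall back to the maximum-clade family (the only expression
    form available for that arity); the component set records which family
    was used via the expressions themselves.  Apomorphy-based definitions
    are not convertible to expressions and raise
    :class:`UnsupportedPhylorefType`.
    """
    phyloref_id = p.id or ""
    internals = list(p.internal_specifiers)
    externals = list(p.external_specifiers)
    if p.phyloref_type == "apomorphy-based":
        raise UnsupportedPhylorefType(
            "apomorphy-based clade definitions are not supported for expression generation"
        )
    if p.phyloref_type == "minimum-clade":
        if len(internals) == 1 and externals:
            return max_clade_components(internals, externals, phyloref_id)
        return min_clade_components(internals, phyloref_id)
    if p.phyloref_type == "maximum-clade":
        return max_clade_components(internals, externals, phyloref_id)
    raise UnsupportedPhylorefType(f"unknown phyloreference type {p.phyloref_type!r}")
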