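"""Reading, validating and serializing Phyx documents.

A Phyx document is a JSON-LD file bundling phylogenies (as Newick
strings plus metadata) with phyloreferences (structured clade
definitions).  This module parses such documents into typed objects,
collects structured validation findings (JSON path, severity, message),
writes documents back out, and converts a document into its
ontology-structured JSON-LD form: ontology metadata is injected, every
tree node becomes a node individual with child/descendant links and
represents-TU annotations, and each phyloreference gains its generated
component class expressions.

Fields marked as software-only in the format tables (specifier lists,
``expectedResolution``, ``additionalNodeProperties``) survive the native
round-trip but are consumed — not emitted — by the ontology conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Dict, List, Optional, Tuple

from . import terms
from .clade_expressions import (
    ComponentSet,
    NodeClassExpression,
    IncludesTU,
    ExcludesTU,
    ExcludesLineageTo,
    HasChild,
    HasAncestor,
    And,
    UnsupportedPhylorefType,
    phyloref_to_components,
)
from .taxonomic_units import Apomorphy, TaxonomicUnit
from .tree_model import NewickParseError, UnsupportedNewickFeature, parse_newick

__all__ = [
    "Severity",
    "Finding",
    "Citation",
    "ExpectedResolution",
    "Phylogeny",
    "Phyloreference",
    "PhyxDocument",
    "PhyxValidationError",
    "parse_phyx",
    "load_phyx",
    "serialize_phyx",
    "mint_ids",
    "to_ontology",
]


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Finding:
    """One validation finding, addressed by JSON path."""

    path: str
    severity: Severity
    message: str

    def __str__(self) -> str:
        return f"{self.severity.value.upper()} {self.path}: {self.message}"


class PhyxValidationError(ValueError):
    """Raised by :func:`load_phyx` when hard errors are present."""

    def __init__(self, findings: List[Finding]):
        self.findings = findings
        errors = [f for f in findings if f.severity is Severity.ERROR]
        super().__init__(
            "; ".join(str(f) for f in errors) or "invalid Phyx document"
        )


# ---------------------------------------------------------------------------
# Document types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Citation:
    """A BibJSON-style citation.

    The raw field dictionary is preserved; ``bibliographic_citation``
    renders the reference as ``"Authors (Year) Title. Journal."`` when no
    explicit ``bibliographicCitation`` value is present.
    """

    fields: Dict[str, Any] = field(default_factory=dict)

    def __eq__(self, other):
        return isinstance(other, Citation) and self.fields == other.fields

    def __hash__(self):
        return hash(json.dumps(self.fields, sort_keys=True))

    @property
    def bibliographic_citation(self) -> str:
        explicit = self.fields.get("bibliographicCitation")
        if explicit:
            return explicit
        authors = self.fields.get("authors", [])
        names = []
        for a in authors:
            if isinstance(a, dict):
                names.append(a.get("name") or " ".join(
                    p for p in (a.get("firstname"), a.get("lastname")) if p))
            else:
                names.append(str(a))
        parts = []
        if names:
            parts.append(", ".join(n for n in names if n))
        year = self.fields.get("year")
        if year:
            parts.append(f"({year})")
        rendered = " ".join(parts)
        title = self.fields.get("title")
        if title:
            rendered = (rendered + " " if rendered else "") + title.rstrip(".") + "."
        journal = self.fields.get("journal")
        if isinstance(journal, dict):
            journal = journal.get("name")
        if journal:
            rendered += f" {journal}."
        return rendered

    def to_jsonld(self) -> Dict[str, Any]:
        return dict(self.fields)


@dataclass(frozen=True)
class ExpectedResolution:
    node_label: str
    description: Optional[str] = None


@dataclass
class Phylogeny:
    """A rooted phylogeny carried as a Newick string plus metadata."""

    newick: str
    id: Optional[str] = None
    label: Optional[str] = None
    source: Optional[Citation] = None
    additional_node_properties: Dict[str, Dict[str, Any]] = field(default_factory=dict)

    def tree(self):
        return parse_newick(self.newick)

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {}
        if self.id:
            out["@id"] = self.id
        if self.label:
            out["label"] = self.label
        out["newick"] = self.newick
        if self.source:
            out["source"] = self.source.to_jsonld()
        if self.additional_node_properties:
            out["additionalNodeProperties"] = self.additional_node_properties
        return out


PHYLOREF_TYPE_ALIASES = {
    "minimum-clade": "minimum-clade",
    "maximum-clade": "maximum-clade",
    "apomorphy-based": "apomorphy-based",
    terms.PHYLOREF_MINIMUM_CLADE: "minimum-clade",
    terms.PHYLOREF_MAXIMUM_CLADE: "maximum-clade",
    terms.PHYLOREF_APOMORPHY: "apomorphy-based",
    terms.expand(terms.PHYLOREF_MINIMUM_CLADE): "minimum-clade",
    terms.expand(terms.PHYLOREF_MAXIMUM_CLADE): "maximum-clade",
    terms.expand(terms.PHYLOREF_APOMORPHY): "apomorphy-based",
}

PHYLOREF_TYPE_CURIES = {
    "minimum-clade": terms.PHYLOREF_MINIMUM_CLADE,
    "maximum-clade": terms.PHYLOREF_MAXIMUM_CLADE,
    "apomorphy-based": terms.PHYLOREF_APOMORPHY,
}


@dataclass
class Phyloreference:
    """A structured clade definition."""

    definition: str
    phyloref_type: str  # 'minimum-clade' | 'maximum-clade' | 'apomorphy-based'
    id: Optional[str] = None
    label: Optional[str] = None
    internal_specifiers: List[TaxonomicUnit] = field(default_factory=list)
    external_specifiers: List[TaxonomicUnit] = field(default_factory=list)
    apomorphy: Optional[Apomorphy] = None
    scientific_name_authorship: Optional[Citation] = None
    name_published_in: Optional[Citation] = None
    definition_source: Optional[Citation] = None
    expected_resolution: Dict[str, ExpectedResolution] = field(default_factory=dict)

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {}
        if self.id:
            out["@id"] = self.id
        if self.label:
            out["label"] = self.label
        out["phylorefType"] = PHYLOREF_TYPE_CURIES[self.phyloref_type]
        out["definition"] = self.definition
        if self.internal_specifiers:
            out["internalSpecifiers"] = [tu.to_jsonld() for tu in self.internal_specifiers]
        if self.external_specifiers:
            out["externalSpecifiers"] = [tu.to_jsonld() for tu in self.external_specifiers]
        if self.apomorphy:
            apo: Dict[str, Any] = {"@type": self.apomorphy.type, "definition": self.apomorphy.definition}
            if self.apomorphy.bearingEntity:
                apo["bearingEntity"] = self.apomorphy.bearingEntity
            apo["phenotypicQuality"] = self.apomorphy.phenotypicQuality
            out["apomorphy"] = apo
        for key, cite in (
            ("scientificNameAuthorship", self.scientific_name_authorship),
            ("namePublishedIn", self.name_published_in),
            ("definitionSource", self.definition_source),
        ):
            if cite:
                out[key] = cite.to_jsonld()
        if self.expected_resolution:
            out["expectedResolution"] = {
                k: {"nodeLabel": v.node_label, **({"description": v.description} if v.description else {})}
                for k, v in self.expected_resolution.items()
            }
        return out


@dataclass
class PhyxDocument:
    """A parsed Phyx document."""

    context: str
    types: List[str] = field(default_factory=list)
    imports: List[str] = field(default_factory=list)
    doi: Optional[str] = None
    source: Optional[Citation] = None
    default_nomenclatural_code: Optional[str] = None
    phylogenies: List[Phylogeny] = field(default_factory=list)
    phylorefs: List[Phyloreference] = field(default_factory=list)

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"@context": self.context}
        if self.types:
            out["@type"] = list(self.types)
        if self.imports:
            out["owl:imports"] = list(self.imports)
        if self.doi:
            out["doi"] = self.doi
        if self.source:
            out["source"] = self.source.to_jsonld()
        if self.default_nomenclatural_code:
            out["defaultNomenclaturalCodeIRI"] = self.default_nomenclatural_code
        if self.phylogenies:
            out["phylogenies"] = [p.to_jsonld() for p in self.phylogenies]
        if self.phylorefs:
            out["phylorefs"] = [p.to_jsonld() for p in self.phylorefs]
        return out


# ---------------------------------------------------------------------------
# Parsing and validation
# ---------------------------------------------------------------------------

_KNOWN_DOC_FIELDS = {
    "@context", "@type", "@id", "owl:imports", "doi", "source",
    "defaultNomenclaturalCodeIRI", "phylogenies", "phylorefs",
}
_KNOWN_PHYLOGENY_FIELDS = {"@id", "label", "newick", "source", "additionalNodeProperties"}
_KNOWN_PHYLOREF_FIELDS = {
    "@id", "label", "phylorefType", "definition", "internalSpecifiers",
    "externalSpecifiers", "apomorphy", "scientificNameAuthorship",
    "namePublishedIn", "definitionSource", "expectedResolution",
}


def _as_list(value) -> List[Any]:
    if value is None:
        return []
    return value if isinstance(value, list) else [value]


def parse_phyx(data: Any) -> Tuple[Optional[PhyxDocument], List[Finding]]:
    """Parse a JSON object (or JSON text) into a document plus findings.

    Never raises on content problems: hard problems come back as
    ERROR-severity findings (and, if the document is structurally
    unusable, a ``None`` document).  The default nomenclatural code is
    propagated to taxon names that lack one.
    """
    if isinstance(data, (str, bytes)):
        data = json.loads(data)
    findings: List[Finding] = []
    if not isinstance(data, dict):
        findings.append(Finding("/", Severity.ERROR, "a Phyx document must be a JSON object"))
        return None, findings

    for key in data:
        if key not in _KNOWN_DOC_FIELDS:
            findings.append(Finding(f"/{key}", Severity.WARNING, f"unknown document field {key!r}"))

    context = data.get("@context")
    if not context:
        findings.append(Finding("/@context", Severity.ERROR,
                                "missing required '@context' (the JSON-LD context IRI)"))
        context = ""

    default_code = data.get("defaultNomenclaturalCodeIRI")
    doc = PhyxDocument(
        context=context,
        types=_as_list(data.get("@type")),
        imports=_as_list(data.get("owl:imports")),
        doi=data.get("doi"),
        source=Citation(data["source"]) if isinstance(data.get("source"), dict) else None,
        default_nomenclatural_code=default_code,
    )

    for i, raw in enumerate(_as_list(data.get("phylogenies"))):
        path = f"/phylogenies/{i}"
        if not isinstance(raw, dict):
            findings.append(Finding(path, Severity.ERROR, "phylogeny must be a JSON object"))
            continue
        for key in raw:
            if key not in _KNOWN_PHYLOGENY_FIELDS:
                findings.append(Finding(f"{path}/{key}", Severity.WARNING,
                                        f"unknown phylogeny field {key!r}"))
        newick = raw.get("newick")
        if not newick:
            findings.append(Finding(f"{path}/newick", Severity.ERROR,
                                    "missing required 'newick' (the Newick string)"))
            continue
        phylogeny = Phylogeny(
            newick=newick,
            id=raw.get("@id"),
            label=raw.get("label"),
            source=Citation(raw["source"]) if isinstance(raw.get("source"), dict) else None,
            additional_node_properties=raw.get("additionalNodeProperties", {}) or {},
        )
        try:
            tree = phylogeny.tree()
        except (NewickParseError, UnsupportedNewickFeature) as exc:
            findings.append(Finding(f"{path}/newick", Severity.ERROR, f"invalid Newick: {exc}"))
            doc.phylogenies.append(phylogeny)
            continue
        labels = {n.label for n in tree.nodes() if n.label}
        for key in phylogeny.additional_node_properties:
            if key not in labels:
                findings.append(Finding(
                    f"{path}/additionalNodeProperties/{key}", Severity.WARNING,
                    f"no node labeled {key!r} in this phylogeny"))
        doc.phylogenies.append(phylogeny)

    for i, raw in enumerate(_as_list(data.get("phylorefs"))):
        path = f"/phylorefs/{i}"
        if not isinstance(raw, dict):
            findings.append(Finding(path, Severity.ERROR, "phyloreference must be a JSON object"))
            continue
        for key in raw:
            if key not in _KNOWN_PHYLOREF_FIELDS:
                findings.append(Finding(f"{path}/{key}", Severity.WARNING,
                                        f"unknown phyloreference field {key!r}"))
        definition = raw.get("definition")
        if not definition:
            findings.append(Finding(f"{path}/definition", Severity.ERROR,
                                    "missing required 'definition' (the verbatim clade definition)"))
            definition = ""
        raw_type = raw.get("phylorefType")
        if raw_type is None and raw.get("apomorphy"):
            raw_type = "apomorphy-based"
        phyloref_type = PHYLOREF_TYPE_ALIASES.get(raw_type or "")
        if phyloref_type is None:
            findings.append(Finding(f"{path}/phylorefType", Severity.ERROR,
                                    f"unknown phylorefType {raw_type!r}"))
            continue

        def _specs(key: str) -> List[TaxonomicUnit]:
            out = []
            for j, spec in enumerate(_as_list(raw.get(key))):
                try:
                    out.append(TaxonomicUnit.from_jsonld(spec, default_code))
                except (ValueError, TypeError) as exc:
                    findings.append(Finding(f"{path}/{key}/{j}", Severity.ERROR,
                                            f"invalid specifier: {exc}"))
            return out

        internals = _specs("internalSpecifiers")
        externals = _specs("externalSpecifiers")

        apomorphy = None
        if isinstance(raw.get("apomorphy"), dict):
            apo = raw["apomorphy"]
            if not apo.get("definition"):
                findings.append(Finding(f"{path}/apomorphy/definition", Severity.ERROR,
                                        "missing required apomorphy 'definition'"))
            else:
                apomorphy = Apomorphy(
                    definition=apo["definition"],
                    type=apo.get("@type", terms.SIO_PHENOTYPE),
                    bearingEntity=apo.get("bearingEntity"),
                    phenotypicQuality=apo.get("phenotypicQuality", terms.PATO_PRESENT),
                )

        # arity rules per clade-definition type
        if phyloref_type == "apomorphy-based":
            if len(internals) != 1 or externals:
                findings.append(Finding(
                    f"{path}/internalSpecifiers", Severity.ERROR,
                    "an apomorphy-based phyloreference requires exactly one internal "
                    f"specifier and no external specifiers (got {len(internals)} internal, "
                    f"{len(externals)} external)"))
            if apomorphy is None and not raw.get("apomorphy"):
                findings.append(Finding(f"{path}/apomorphy", Severity.ERROR,
                                        "an apomorphy-based phyloreference requires an apomorphy"))
        elif phyloref_type == "minimum-clade":
            if len(internals) < 2 and not (len(internals) == 1 and externals):
                findings.append(Finding(
                    f"{path}/internalSpecifiers", Severity.ERROR,
                    "a minimum-clade phyloreference requires at least two internal "
                    "specifiers (or one internal plus at least one external)"))
        elif phyloref_type == "maximum-clade":
            if not internals or not externals:
                findings.append(Finding(
                    f"{path}/internalSpecifiers", Severity.ERROR,
                    "a maximum-clade phyloreference requires at least one internal "
                    "and one external specifier"))

        expected: Dict[str, ExpectedResolution] = {}
        for key, val in (raw.get("expectedResolution") or {}).items():
            if not isinstance(val, dict) or "nodeLabel" not in val:
                findings.append(Finding(f"{path}/expectedResolution/{key}", Severity.ERROR,
                                        "expectedResolution entries need a 'nodeLabel'"))
                continue
            expected[key] = ExpectedResolution(node_label=val["nodeLabel"],
                                               description=val.get("description"))

        doc.phylorefs.append(Phyloreference(
            definition=definition,
            phyloref_type=phyloref_type,
            id=raw.get("@id"),
            label=raw.get("label"),
            internal_specifiers=internals,
            external_specifiers=externals,
            apomorphy=apomorphy,
            scientific_name_authorship=Citation(raw["scientificNameAuthorship"])
                if isinstance(raw.get("scientificNameAuthorship"), dict) else None,
            name_published_in=Citation(raw["namePublishedIn"])
                if isinstance(raw.get("namePublishedIn"), dict) else None,
            definition_source=Citation(raw["definitionSource"])
                if isinstance(raw.get("definitionSource"), dict) else None,
            expected_resolution=expected,
        ))

    # document-level cross-references and id uniqueness
    phylogeny_ids = {p.id for p in doc.phylogenies if p.id}
    for i, p in enumerate(doc.phylorefs):
        for key in p.expected_resolution:
            if key not in phylogeny_ids:
                findings.append(Finding(
                    f"/phylorefs/{i}/expectedResolution/{key}", Severity.ERROR,
                    f"expectedResolution refers to phylogeny {key!r}, which is not "
                    "present in this document"))
    seen_ids: Dict[str, str] = {}
    for kind, items in (("phylogenies", doc.phylogenies), ("phylorefs", doc.phylorefs)):
        for i, item in enumerate(items):
            if item.id:
                if item.id in seen_ids:
                    findings.append(Finding(f"/{kind}/{i}/@id", Severity.ERROR,
                                            f"duplicate id {item.id!r} (also used by {seen_ids[item.id]})"))
                else:
                    seen_ids[item.id] = f"/{kind}/{i}"

    return doc, findings


def load_phyx(text: Any) -> PhyxDocument:
    """Parse and validate; raise :class:`PhyxValidationError` on hard errors."""
    doc, findings = parse_phyx(text)
    if doc is None or any(f.severity is Severity.ERROR for f in findings):
        raise PhyxValidationError(findings)
    return doc


def serialize_phyx(doc: PhyxDocument, indent: int = 2) -> str:
    """Serialize back to Phyx JSON-LD text (a fixed point under load)."""
    return json.dumps(doc.to_jsonld(), indent=indent, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# Id minting
# ---------------------------------------------------------------------------

def mint_ids(doc: PhyxDocument) -> PhyxDocument:
    """Assign deterministic fragment IRIs to entities lacking one.

    Phylogenies become ``#phylogeny<i>`` and phyloreferences
    ``#phyloref<i>``, indexed by document order; existing ids are left
    untouched (so minting is idempotent).  Tree-node individuals are
    minted at ontology-conversion time as ``<phylogeny id>_node<i>`` in
    preorder.  A collision after minting raises ``ValueError``.
    """
    for i, phylogeny in enumerate(doc.phylogenies):
        if not phylogeny.id:
            phylogeny.id = f"#phylogeny{i}"
    for i, phyloref in enumerate(doc.phylorefs):
        if not phyloref.id:
            phyloref.id = f"#phyloref{i}"
    ids = [p.id for p in doc.phylogenies] + [p.id for p in doc.phylorefs]
    duplicates = {x for x in ids if ids.count(x) > 1}
    if duplicates:
        raise ValueError(f"id collision after minting: {sorted(duplicates)}")
    return doc


# ---------------------------------------------------------------------------
# Ontology conversion
# ---------------------------------------------------------------------------

def _tu_owl_expression(tu: TaxonomicUnit) -> Dict[str, Any]:
    """The OWL-style logical form of one specifier."""
    if tu.taxon_concept is not None:
        tc = tu.taxon_concept
        operands: List[Dict[str, Any]] = []
        if tc.hasName.nomenclaturalCode:
            operands.append({"@type": "owl:Restriction",
                             "onProperty": "tn:nomenclaturalCode",
                             "hasValue": {"@id": tc.hasName.nomenclaturalCode}})
        operands.append({"@type": "owl:Restriction",
                         "onProperty": "tc:nameComplete",
                         "hasValue": tc.hasName.nameComplete})
        if tc.nameAccordingTo:
            operands.append({"@type": "owl:Restriction",
                             "onProperty": "tc:accordingTo",
                             "hasValue": tc.nameAccordingTo})
        inner: Dict[str, Any] = (
            operands[0] if len(operands) == 1
            else {"@type": "owl:Class", "intersectionOf": operands}
        )
        return {"@type": "owl:Restriction", "onProperty": "tc:hasName",
                "someValuesFrom": inner}
    if tu.specimen is not None:
        from .taxonomic_units import occurrence_id
        return {"@type": "owl:Restriction", "onProperty": "dwc:occurrenceID",
                "hasValue": occurrence_id(tu.specimen)}
    return {"@id": tu.id}


def expression_to_jsonld(expr: NodeClassExpression) -> Dict[str, Any]:
    """Serialize a node-class expression as OWL-structured JSON-LD."""
    if isinstance(expr, IncludesTU):
        return {"@type": "owl:Restriction", "onProperty": terms.PHYLOREF_INCLUDES_TU,
                "someValuesFrom": _tu_owl_expression(expr.tu)}
    if isinstance(expr, ExcludesTU):
        return {"@type": "owl:Restriction", "onProperty": terms.PHYLOREF_EXCLUDES_TU,
                "someValuesFrom": _tu_owl_expression(expr.tu)}
    if isinstance(expr, ExcludesLineageTo):
        return {"@type": "owl:Restriction", "onProperty": terms.PHYLOREF_EXCLUDES_LINEAGE_TO,
                "someValuesFrom": expression_to_jsonld(expr.expr)}
    if isinstance(expr, HasChild):
        return {"@type": "owl:Restriction", "onProperty": terms.CDAO_HAS_CHILD,
                "someValuesFrom": expression_to_jsonld(expr.expr)}
    if isinstance(expr, HasAncestor):
        return {"@type": "owl:Restriction", "onProperty": terms.CDAO_HAS_ANCESTOR,
                "someValuesFrom": expression_to_jsonld(expr.expr)}
    if isinstance(expr, And):
        return {"@type": "owl:Class",
                "intersectionOf": [expression_to_jsonld(op) for op in expr.operands]}
    raise TypeError(f"unknown expression type {type(expr).__name__}")


def to_ontology(doc: PhyxDocument) -> Tuple[Dict[str, Any], List[Finding]]:
    """Convert a validated, id-minted document to ontology JSON-LD.

    Returns the ontology dictionary and any conversion findings (for
    example the recorded "unsupported" finding for an apomorphy-based
    phyloreference, whose expression generation is skipped).
    """
    findings: List[Finding] = []
    mint_ids(doc)
    out: Dict[str, Any] = {"@context": doc.context}
    out["@type"] = [terms.OWL_ONTOLOGY] + [t for t in doc.types if t != terms.OWL_ONTOLOGY]
    imports = [terms.PHYLOREF_ONTOLOGY, terms.TCAN_ONTOLOGY]
    out["owl:imports"] = imports + [i for i in doc.imports if i not in imports]
    if doc.doi:
        out["doi"] = doc.doi
    if doc.source:
        out["source"] = {"bibliographicCitation": doc.source.bibliographic_citation}

    phylogenies_out = []
    for phylogeny in doc.phylogenies:
        tree = phylogeny.tree()
        nodes = list(tree.nodes())
        index = {node.node_id: i for i, node in enumerate(nodes)}
        node_entries = []
        for i, node in enumerate(nodes):
            entry: Dict[str, Any] = {
                "@id": f"{phylogeny.id}_node{i}",
                "@type": [terms.CDAO_NODE],
            }
            if node.label:
                entry["rdfs:label"] = node.label
            if node.children:
                entry[terms.CDAO_HAS_CHILD] = [
                    {"@id": f"{phylogeny.id}_node{index[c.node_id]}"} for c in node.children
                ]
                entry[terms.CDAO_HAS_DESCENDANT] = [
                    {"@id": f"{phylogeny.id}_node{index[d.node_id]}"}
                    for d in sorted(
                        (d for d in node.walk() if d is not node),
                        key=lambda d: index[d.node_id],
                    )
                ]
            tus = _node_taxonomic_units(phylogeny, node, doc.default_nomenclatural_code)
            if tus:
                entry[terms.CDAO_REPRESENTS_TU] = [
                    {"someValuesFrom": _tu_owl_expression(tu)} for tu in tus
                ]
            node_entries.append(entry)
        entry: Dict[str, Any] = {"@id": phylogeny.id, "newick": phylogeny.newick}
        if phylogeny.label:
            entry["label"] = phylogeny.label
        if phylogeny.source:
            entry["source"] = {"bibliographicCitation": phylogeny.source.bibliographic_citation}
        entry["nodes"] = node_entries
        phylogenies_out.append(entry)
    if phylogenies_out:
        out["phylogenies"] = phylogenies_out

    phylorefs_out = []
    for phyloref in doc.phylorefs:
        entry = {
            "@id": phyloref.id,
            "@type": ["owl:Class", PHYLOREF_TYPE_CURIES[phyloref.phyloref_type]],
            "definition": phyloref.definition,
        }
        if phyloref.label:
            entry["label"] = phyloref.label
        try:
            component_set = phyloref_to_components(phyloref)
        except UnsupportedPhylorefType as exc:
            findings.append(Finding(
                f"/phylorefs/{doc.phylorefs.index(phyloref)}", Severity.WARNING,
                f"unsupported: {exc}"))
            component_set = ComponentSet(phyloref_id=phyloref.id or "")
        components = []
        for j, expr in enumerate(component_set.components):
            components.append({
                "@id": f"{phyloref.id}_component{j}",
                "@type": ["owl:Class"],
                "rdfs:subClassOf": {"@id": phyloref.id},
                "equivalentClass": expression_to_jsonld(expr),
            })
        if components:
            entry["components"] = components
        phylorefs_out.append(entry)
    if phylorefs_out:
        out["phylorefs"] = phylorefs_out
    return out, findings


def _node_taxonomic_units(phylogeny: Phylogeny, node, default_code: Optional[str]) -> List[TaxonomicUnit]:
    """TUs a node represents: its parsed label plus any additional properties."""
    from .resolution import node_taxonomic_units  # single source of truth

    return node_taxonomic_units(phylogeny, node, default_code)
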