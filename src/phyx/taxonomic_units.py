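"""Taxonomic units: the anchors that tie clade definitions to trees.

A taxonomic unit (TU) is anything that can be matched to a node of a
phylogeny.  Three kinds are supported, mirroring the exchange format:

* an opaque IRI (``@id`` only),
* a taxon concept — a scientific name plus an optional circumscription
  citation (``nameAccordingTo``),
* a specimen — a Darwin Core occurrence, identified by ``occurrenceID`` or
  by the institution/collection/catalog "Darwin Core Triplet".

Two TUs *match* when any of three facet comparisons succeeds: identical
``nameComplete`` strings, identical ``@id`` IRIs, or identical occurrence
identifiers.  Matching is deliberately shallow — no synonym or fuzzy-name
logic — because resolution correctness must not depend on external
taxonomic services.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Dict, Optional

from . import terms

__all__ = [
    "TaxonName",
    "TaxonConcept",
    "Specimen",
    "TaxonomicUnit",
    "Apomorphy",
    "TaxonNameParseError",
    "SpecimenIdentifierError",
    "parse_taxon_name",
    "occurrence_id",
    "match_tu",
]


class TaxonNameParseError(ValueError):
    """The verbatim string could not be read as a scientific name."""


class SpecimenIdentifierError(ValueError):
    """A specimen carries no identifier material at all."""


@dataclass(frozen=True)
class TaxonName:
    """A uninomial, binomial or trinomial scientific name.

    ``nameComplete`` never contains authority or year components; the full
    verbatim form (with authority) is kept in ``label``.
    """

    nameComplete: str
    genusPart: Optional[str] = None
    specificEpithet: Optional[str] = None
    nomenclaturalCode: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self):
        if not self.nameComplete or not self.nameComplete.strip():
            raise ValueError("nameComplete must be non-empty")
        if self.genusPart and self.specificEpithet:
            expected = f"{self.genusPart} {self.specificEpithet}"
            if not self.nameComplete.startswith(expected):
                raise ValueError(
                    f"nameComplete {self.nameComplete!r} does not start with "
                    f"'genusPart specificEpithet' = {expected!r}"
                )

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"@type": terms.TN_TAXON_NAME, "nameComplete": self.nameComplete}
        if self.nomenclaturalCode:
            out["nomenclaturalCode"] = self.nomenclaturalCode
        if self.genusPart:
            out["genusPart"] = self.genusPart
        if self.specificEpithet:
            out["specificEpithet"] = self.specificEpithet
        if self.label:
            out["label"] = self.label
        return out


@dataclass(frozen=True)
class TaxonConcept:
    """A taxon name plus an optional circumscription.

    When ``nameAccordingTo`` is omitted the nominal taxon concept is
    assumed.
    """

    hasName: TaxonName
    nameAccordingTo: Optional[str] = None

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"@type": terms.TC_TAXON_CONCEPT, "hasName": self.hasName.to_jsonld()}
        if self.nameAccordingTo:
            out["nameAccordingTo"] = self.nameAccordingTo
        return out


@dataclass(frozen=True)
class Specimen:
    """A Darwin Core occurrence record used as a specifier."""

    occurrenceID: Optional[str] = None
    institutionCode: Optional[str] = None
    collectionCode: Optional[str] = None
    catalogNumber: Optional[str] = None
    hasName: Optional[TaxonName] = None

    def to_jsonld(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"@type": terms.DWC_OCCURRENCE}
        for key in ("occurrenceID", "institutionCode", "collectionCode", "catalogNumber"):
            value = getattr(self, key)
            if value:
                out[key] = value
        if self.hasName:
            out["hasName"] = self.hasName.to_jsonld()
        return out


@dataclass(frozen=True)
class Apomorphy:
    """A derived trait anchoring an apomorphy-based clade definition."""

    definition: str
    type: str = terms.SIO_PHENOTYPE
    bearingEntity: Optional[str] = None
    phenotypicQuality: str = terms.PATO_PRESENT

    def __post_init__(self):
        if not self.definition or not self.definition.strip():
            raise ValueError("apomorphy definition must be non-empty")


@dataclass(frozen=True)
class TaxonomicUnit:
    """A matchable unit of taxonomy: IRI-only, taxon concept, or specimen.

    An IRI-only unit has ``id`` set and no payload; a payload-bearing unit
    may also carry an ``id``.
    """

    id: Optional[str] = None
    taxon_concept: Optional[TaxonConcept] = None
    specimen: Optional[Specimen] = None

    def __post_init__(self):
        if self.taxon_concept is not None and self.specimen is not None:
            raise ValueError("a taxonomic unit holds at most one payload")
        if self.id is None and self.taxon_concept is None and self.specimen is None:
            raise ValueError("a taxonomic unit needs an @id or a payload")

    # -- convenience constructors ----------------------------------------

    @classmethod
    def from_name(cls, name: str, default_code: Optional[str] = None) -> "TaxonomicUnit":
        return cls(taxon_concept=TaxonConcept(hasName=parse_taxon_name(name, default_code)))

    @classmethod
    def from_iri(cls, iri: str) -> "TaxonomicUnit":
        return cls(id=iri)

    @classmethod
    def from_specimen(cls, **kwargs) -> "TaxonomicUnit":
        return cls(specimen=Specimen(**kwargs))

    # -- facets -----------------------------------------------------------

    @property
    def name_complete(self) -> Optional[str]:
        if self.taxon_concept is not None:
            return self.taxon_concept.hasName.nameComplete
        if self.specimen is not None and self.specimen.hasName is not None:
            return self.specimen.hasName.nameComplete
        return None

    def describe(self) -> str:
        if self.taxon_concept is not None:
            return self.taxon_concept.hasName.nameComplete
        if self.specimen is not None:
            try:
                return f"specimen {occurrence_id(self.specimen)}"
            except SpecimenIdentifierError:
                return "specimen (unidentified)"
        return str(self.id)

    def to_jsonld(self) -> Dict[str, Any]:
        if self.taxon_concept is not None:
            out = self.taxon_concept.to_jsonld()
        elif self.specimen is not None:
            out = self.specimen.to_jsonld()
        else:
            out = {}
        if self.id:
            out = {"@id": self.id, **out}
        return out

    @classmethod
    def from_jsonld(cls, data: Dict[str, Any], default_code: Optional[str] = None) -> "TaxonomicUnit":
        """Build a TU from its dictionary form, detecting its kind."""
        tu_id = data.get("@id")
        type_iri = data.get("@type", "")
        if isinstance(type_iri, list):
            type_iri = type_iri[0] if type_iri else ""
        if "occurrenceID" in data or "catalogNumber" in data or "institutionCode" in data \
                or type_iri == terms.DWC_OCCURRENCE:
            name = _name_from_jsonld(data.get("hasName"), default_code)
            return cls(
                id=tu_id,
                specimen=Specimen(
                    occurrenceID=data.get("occurrenceID"),
                    institutionCode=data.get("institutionCode"),
                    collectionCode=data.get("collectionCode"),
                    catalogNumber=data.get("catalogNumber"),
                    hasName=name,
                ),
            )
        if "hasName" in data or "nameComplete" in data:
            name = _name_from_jsonld(data.get("hasName", data), default_code)
            return cls(id=tu_id, taxon_concept=TaxonConcept(
                hasName=name, nameAccordingTo=data.get("nameAccordingTo")))
        if tu_id:
            return cls(id=tu_id)
        raise ValueError(f"cannot interpret taxonomic unit: {data!r}")


def _name_from_jsonld(data: Optional[Dict[str, Any]], default_code: Optional[str]) -> Optional[TaxonName]:
    if data is None:
        return None
    if "nameComplete" in data:
        return TaxonName(
            nameComplete=_squash_ws(data["nameComplete"]),
            genusPart=data.get("genusPart"),
            specificEpithet=data.get("specificEpithet"),
            nomenclaturalCode=data.get("nomenclaturalCode") or default_code,
            label=data.get("label"),
        )
    if "label" in data:
        return parse_taxon_name(data["label"], default_code)
    raise ValueError(f"taxon name needs nameComplete or label: {data!r}")


# ---------------------------------------------------------------------------
# Name parsing
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"^(?P<genus>[A-Z][a-zA-Z-]+|[A-Z])"          # capitalized uninomial / genus
    r"(?:\s+(?P<species>[a-z][a-z-]+)"            # specific epithet
    r"(?:\s+(?P<infra>[a-z][a-z-]+))?)?"          # infraspecific epithet
    r"(?P<rest>\s+.*)?$",                         # trailing authority / year
    re.DOTALL,
)


def _squash_ws(text: str) -> str:
    return " ".join(text.split())


def parse_taxon_name(verbatim: str, default_code: Optional[str] = None) -> TaxonName:
    """Split a verbatim scientific name into its structured parts.

    Recognizes uninomials, binomials and trinomials with an optional
    trailing authority, e.g. ``"Alligator mississippiensis (Daudin, 1802)"``.
    The authority is kept only in ``label``; ``nameComplete`` is the bare
    name.  Raises :class:`TaxonNameParseError` when the string does not
    begin with a capitalized word.
    """
    if not verbatim or not verbatim.strip():
        raise TaxonNameParseError("empty taxon name")
    cleaned = _squash_ws(verbatim)
    match = _NAME_RE.match(cleaned)
    if match is None:
        raise TaxonNameParseError(
            f"{verbatim!r} does not start with a capitalized name word"
        )
    genus = match.group("genus")
    species = match.group("species")
    infra = match.group("infra")
    parts = [genus] + [p for p in (species, infra) if p]
    name_complete = " ".join(parts)
    has_authority = bool(match.group("rest") and match.group("rest").strip())
    return TaxonName(
        nameComplete=name_complete,
        genusPart=genus if species else None,
        specificEpithet=species,
        nomenclaturalCode=default_code,
        label=cleaned if has_authority else None,
    )


# ---------------------------------------------------------------------------
# Specimen identifiers
# ---------------------------------------------------------------------------

def occurrence_id(spec: Specimen) -> str:
    """The specimen's occurrence identifier.

    A directly supplied ``occurrenceID`` always wins; otherwise the Darwin
    Core Triplet parts are joined with ``':'``, omitting leading empty
    parts (so institution+catalog yields ``"INST:CAT"``).
    """
    if spec.occurrenceID:
        return spec.occurrenceID
    parts = [spec.institutionCode, spec.collectionCode, spec.catalogNumber]
    present = [p for p in parts if p]
    if not spec.catalogNumber or not present:
        raise SpecimenIdentifierError(
            "specimen has neither an occurrenceID nor a catalogNumber"
        )
    return ":".join(present)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _match_by_name(a: TaxonomicUnit, b: TaxonomicUnit) -> bool:
    na, nb = a.name_complete, b.name_complete
    return na is not None and nb is not None and _squash_ws(na) == _squash_ws(nb)


def _match_by_id(a: TaxonomicUnit, b: TaxonomicUnit) -> bool:
    return a.id is not None and b.id is not None and a.id == b.id


def _match_by_occurrence(a: TaxonomicUnit, b: TaxonomicUnit) -> bool:
    if a.specimen is None or b.specimen is None:
        return False
    try:
        return occurrence_id(a.specimen) == occurrence_id(b.specimen)
    except SpecimenIdentifierError:
        return False


def match_tu(a: TaxonomicUnit, b: TaxonomicUnit) -> bool:
    """True iff the two units match on any shared facet.

    The three facet comparisons are: identical ``nameComplete`` (exact,
    case-sensitive, internal whitespace collapsed), identical ``@id`` IRIs
    (verbatim), identical occurrence identifiers.  Symmetric by
    construction; units of different kinds with no shared facet simply
    return False.
    """
    return _match_by_name(a, b) or _match_by_id(a, b) or _match_by_occurrence(a, b)
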