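"""Programmatically generated example and test documents.

The centerpiece is a crocodylian example: a published archosaur
phylogeny (as a Newick string with named internal clades) together with
the maximum-clade definition of Alligatoroidea — *Alligator
mississippiensis* and all crocodylians closer to it than to *Crocodylus
niloticus* or *Gavialis gangeticus* — which must resolve to the internal
node labeled "Alligatoroidea".  A deliberately malformed trio
(missing ``@context``, missing ``newick``, bad apomorphy arity)
exercises the validator's findings.

Everything here is built in code; the ``corpus`` writer emits the same
documents to disk deterministically (the seed feeds the one randomized
document, a scheme-labeled random topology).
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Any, Dict, List, Tuple

from . import terms
from .topology_sweep import build_sweep_document, enumerate_topologies, label_scheme

__all__ = [
    "CROCODYLIA_NEWICK",
    "crocodylia_document",
    "minimal_document",
    "malformed_documents",
    "write_corpus",
]

CROCODYLIA_NEWICK = (
    "(Parasuchia,(rauisuchians,Aetosauria,(sphenosuchians,(protosuchians,"
    "(mesosuchians,(Hylaeochampsa,Aegyptosuchus,Stomatosuchus,(Allodaposuchus,"
    "('Gavialis gangeticus',(('Diplocynodon ratelii',('Alligator mississippiensis',"
    "'Caiman crocodilus')Alligatoridae)Alligatoroidea,('Tomistoma schlegelii',"
    "('Osteolaemus tetraspis','Crocodylus niloticus')Crocodylinae)Crocodylidae)"
    "Brevirostres)Crocodylia))Eusuchia)Mesoeucrocodylia)Crocodyliformes)"
    "Crocodylomorpha));"
)


def _taxon(name: str) -> Dict[str, Any]:
    genus, _, epithet = name.partition(" ")
    has_name: Dict[str, Any] = {"@type": terms.TN_TAXON_NAME, "nameComplete": name}
    if epithet:
        has_name["genusPart"] = genus
        has_name["specificEpithet"] = epithet
    return {"@type": terms.TC_TAXON_CONCEPT, "hasName": has_name}


def crocodylia_document() -> Dict[str, Any]:
    """The crocodylian example document, as a plain JSON-able dict."""
    return {
        "@context": terms.PHYX_CONTEXT,
        "defaultNomenclaturalCodeIRI": terms.TN_ICZN,
        "phylogenies": [{
            "@id": "#phylogeny0",
            "label": "Archosaur phylogeny with named crocodylian clades",
            "newick": CROCODYLIA_NEWICK,
        }],
        "phylorefs": [{
            "@id": "#Alligatoroidea",
            "label": "Alligatoroidea",
            "phylorefType": terms.PHYLOREF_MAXIMUM_CLADE,
            "definition": (
                "Alligator mississippiensis and all crocodylians closer to it "
                "than to Crocodylus niloticus or Gavialis gangeticus."
            ),
            "internalSpecifiers": [_taxon("Alligator mississippiensis")],
            "externalSpecifiers": [
                _taxon("Crocodylus niloticus"),
                _taxon("Gavialis gangeticus"),
            ],
            "expectedResolution": {
                "#phylogeny0": {
                    "nodeLabel": "Alligatoroidea",
                    "description": "The named Alligatoroidea node on this phylogeny.",
                }
            },
        }],
    }


def specimen_document() -> Dict[str, Any]:
    """A small document whose phylogeny node carries a specimen TU."""
    return {
        "@context": terms.PHYX_CONTEXT,
        "phylogenies": [{
            "@id": "#phylogeny0",
            "newick": "(('Exodictyon incrassatum','Exodictyon dentatum'),'Leucophanes octoblepharioides');",
            "additionalNodeProperties": {
                "Exodictyon incrassatum": {
                    "representsTaxonomicUnits": [{
                        "@type": terms.DWC_OCCURRENCE,
                        "institutionCode": "UC",
                        "catalogNumber": "Wall 2527, Fiji",
                    }]
                }
            },
        }],
    }


def minimal_document() -> Dict[str, Any]:
    return {"@context": terms.PHYX_CONTEXT}


def malformed_documents() -> Dict[str, Dict[str, Any]]:
    """Deliberately broken documents, keyed by what is wrong with them."""
    missing_context = crocodylia_document()
    del missing_context["@context"]

    missing_newick = crocodylia_document()
    del missing_newick["phylogenies"][0]["newick"]

    bad_apomorphy = {
        "@context": terms.PHYX_CONTEXT,
        "phylorefs": [{
            "@id": "#Testudinata",
            "phylorefType": terms.PHYLOREF_APOMORPHY,
            "definition": "The clade arising with the first complete turtle shell.",
            "internalSpecifiers": [_taxon("Testudo graeca"), _taxon("Chelonia mydas")],
            "apomorphy": {
                "@type": terms.SIO_PHENOTYPE,
                "definition": "A complete turtle shell as inherited by Testudo graeca",
            },
        }],
    }
    return {
        "missing_context": missing_context,
        "missing_newick": missing_newick,
        "bad_apomorphy_arity": bad_apomorphy,
    }


def write_corpus(directory: Path, seed: int = 0) -> List[Path]:
    """Write the fixture corpus to ``directory``; byte-identical per seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    catalog = enumerate_topologies(5)
    topology = catalog.topologies[rng.randrange(len(catalog.topologies))]
    random_doc = build_sweep_document(label_scheme(topology)).to_jsonld()

    documents: List[Tuple[str, Dict[str, Any]]] = [
        ("crocodylia.phyx.json", crocodylia_document()),
        ("specimen.phyx.json", specimen_document()),
        ("minimal.phyx.json", minimal_document()),
        ("sweep-topology.phyx.json", random_doc),
    ]
    documents += [
        (f"malformed-{name}.phyx.json", doc)
        for name, doc in sorted(malformed_documents().items())
    ]
    written = []
    for filename, doc in documents:
        path = directory / filename
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n")
        written.append(path)
    return written
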