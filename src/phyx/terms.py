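"""IRIs and CURIE prefixes used across the exchange format.

These mirror the ontologies the format is mapped to: CDAO for tree
structure, the TDWG taxon-concept/taxon-name vocabularies for names,
Darwin Core for specimens, and the phyloreferencing application ontology
for the clade-definition properties.
"""

PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "CDAO": "http://purl.obolibrary.org/obo/CDAO_",
    "dwc": "http://rs.tdwg.org/dwc/terms/",
    "tc": "http://rs.tdwg.org/ontology/voc/TaxonConcept#",
    "tn": "http://rs.tdwg.org/ontology/voc/TaxonName#",
    "phyloref": "http://ontology.phyloref.org/phyloref.owl#",
    "tcan": "http://ontology.phyloref.org/tcan.owl#",
}

# Default document context for the exchange format.
PHYX_CONTEXT = "http://www.phyloref.org/phyx.js/context/v1.0.0/phyx.json"

# Application ontologies added to owl:imports on conversion.
PHYLOREF_ONTOLOGY = "http://ontology.phyloref.org/phyloref.owl"
TCAN_ONTOLOGY = "http://ontology.phyloref.org/tcan.owl"

OWL_ONTOLOGY = "owl:Ontology"

# CDAO tree vocabulary.
CDAO_NODE = "CDAO:0000140"
CDAO_HAS_CHILD = "CDAO:0000149"
CDAO_HAS_ANCESTOR = "CDAO:0000144"
CDAO_HAS_DESCENDANT = "CDAO:0000174"
CDAO_REPRESENTS_TU = "CDAO:0000187"

# Phyloreferencing properties.
PHYLOREF_HAS_SIBLING = "phyloref:has_Sibling"
PHYLOREF_EXCLUDES_LINEAGE_TO = "phyloref:excludes_lineage_to"
PHYLOREF_EXCLUDES_TU = "phyloref:excludes_TU"
PHYLOREF_INCLUDES_TU = "phyloref:includes_TU"

# Clade-definition types.
PHYLOREF_MINIMUM_CLADE = "phyloref:PhyloreferenceUsingMinimumClade"
PHYLOREF_MAXIMUM_CLADE = "phyloref:PhyloreferenceUsingMaximumClade"
PHYLOREF_APOMORPHY = "phyloref:PhyloreferenceUsingApomorphy"

# Taxon concepts / names / specimens.
TC_TAXON_CONCEPT = "http://rs.tdwg.org/ontology/voc/TaxonConcept#TaxonConcept"
TN_TAXON_NAME = "http://rs.tdwg.org/ontology/voc/TaxonName#TaxonName"
DWC_OCCURRENCE = "http://rs.tdwg.org/dwc/terms/Occurrence"
TN_ICZN = "http://rs.tdwg.org/ontology/voc/TaxonName#ICZN"
TN_ICN = "http://rs.tdwg.org/ontology/voc/TaxonName#ICBN"

# Apomorphy trait typing.
SIO_PHENOTYPE = "https://semanticscience.org/resource/SIO_010056"
PATO_PRESENT = "http://purl.obolibrary.org/obo/PATO_0000467"


def expand(curie: str) -> str:
    """Expand a ``prefix:local`` CURIE to a full IRI (pass through IRIs)."""
    if ":" in curie:
        prefix, local = curie.split(":", 1)
        if prefix in PREFIXES:
            return PREFIXES[prefix] + local
    return curie
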