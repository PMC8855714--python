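"""Load, validate and convert a Phyx document to its ontology form.

Builds the crocodylian example document in memory, checks it (and a
deliberately broken sibling) with the validator, then converts it to
ontology-structured JSON-LD and summarizes what the conversion added.
"""

import json

from phyx import load_phyx, mint_ids, parse_phyx, to_ontology
from phyx.fixtures import crocodylia_document, malformed_documents

doc = load_phyx(json.dumps(crocodylia_document()))
print(f"valid document: {len(doc.phylogenies)} phylogeny, {len(doc.phylorefs)} phyloreference")

# A document missing its Newick string fails with a finding that names
# the exact JSON path, so curators can fix the file directly.
_, findings = parse_phyx(malformed_documents()["missing_newick"])
for finding in findings:
    print(f"broken document -> {finding}")

ontology, _ = to_ontology(mint_ids(doc))
nodes = ontology["phylogenies"][0]["nodes"]
components = ontology["phylorefs"][0]["components"]
print(f"ontology types: {ontology['@type']}")
print(f"node individuals: {len(nodes)} (one per tree node, with child/descendant links)")
print(f"component classes: {len(components)} (one per external specifier)")
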