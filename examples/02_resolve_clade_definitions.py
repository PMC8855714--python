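"""Resolve a digitized clade definition on its reference phylogeny.

The Alligatoroidea definition — Alligator mississippiensis and all
crocodylians closer to it than to Crocodylus niloticus or Gavialis
gangeticus — is a maximum-clade definition with one internal and two
external specifiers.  Resolving it on the bundled archosaur phylogeny
must select exactly the internal node labeled "Alligatoroidea", which
is also what the curator recorded as the expected resolution.
"""

import json

from phyx import annotate, load_phyx, resolve_document, resolve_on_reference_tree
from phyx.fixtures import crocodylia_document

doc = load_phyx(json.dumps(crocodylia_document()))
result = resolve_document(doc)[0]
print(f"phyloreference:  {result.phyloref_id}")
print(f"status:          {result.status.value}")
print(f"resolved to:     {result.resolved_labels}")
print(f"expected:        {result.expected_label} (met: {result.expectation_met})")

# The same definition can be resolved by the two-step name translation +
# MRCA walk used against large synthesis trees (here: the same tree).
at = annotate(doc.phylogenies[0])
node_id = resolve_on_reference_tree(doc.phylorefs[0], at)
print(f"reference-tree walk lands on: {at.label_of(node_id)}")
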