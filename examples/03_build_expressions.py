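"""Generate the logical expressions behind a clade definition.

A minimum-clade definition with n internal specifiers becomes n(n−1)/2
component expressions (disjunction is outside the OWL2 EL profile, so
each disjunct becomes its own component class); a maximum-clade
definition becomes one component per external specifier.  Evaluating
the components directly on a tree shows where the definition resolves.
"""

from phyx import (
    TaxonomicUnit,
    annotate,
    evaluate,
    max_clade_components,
    min_clade_components,
)
from phyx.phyx_document import Phylogeny

A, B, C = (TaxonomicUnit.from_name(x) for x in "ABC")

min3 = min_clade_components([A, B, C])
print(f"minimum clade of {{A,B,C}}: {len(min3.components)} components")
for expr in min3.components:
    print(f"  {expr!r}")

max2 = max_clade_components([A], [B, C])
print(f"maximum clade incl A excl {{B,C}}: {len(max2.components)} components")

# Evaluate on a polytomy: the MRCA of A, B, C is the root.
at = annotate(Phylogeny(newick="((A,B,C),D);"))
resolved = set()
for expr in min3.components:
    resolved |= evaluate(expr, at)
labels = {frozenset(l.label for l in at.tree.node(n).walk() if l.is_leaf)
          for n in resolved}
print(f"on ((A,B,C),D) the union resolves the clade with leaves: {sorted(next(iter(labels)))}")
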