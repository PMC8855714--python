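# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the numerical/design choices made where the
design was genuinely open, and what the test suite does and does not
establish.

## Tree model and Newick dialect

Trees are rooted and ordered, with optional labels and branch lengths on
every node. Resolution semantics are purely topological: branch lengths
are parsed for round-trip fidelity and otherwise ignored. Polytomies and
unifurcations are preserved exactly as written — the format does not
forbid single-child nodes, and all node relations remain well defined on
them.

Dialect decisions:

* Single-quoted labels may contain any character; a doubled quote
  encodes a literal quote. Underscores in *unquoted* labels are read as
  spaces (the classic convention), so `Alligator_mississippiensis`
  matches the taxon name "Alligator mississippiensis".
* Consequently the writer quotes any label containing whitespace,
  structural characters (`( ) [ ] , : ;`), quotes, **or underscores** —
  an unquoted underscore would be read back as a space and break the
  round-trip guarantee `parse(write(t)) ≡ t`, which the suite checks on
  every enumerated topology up to five leaves.
* A missing terminal `;` is tolerated with a warning (common in strings
  embedded in JSON). Square-bracket comments are skipped. Parse errors
  report the 0-based character offset. Extended-Newick reticulation
  tags (`#H1`) are rejected explicitly: phylogenetic networks are out of
  scope.

## Taxonomic units and matching

Three unit kinds: opaque IRI, taxon concept (name + optional
circumscription), specimen (Darwin Core occurrence). Matching is the
disjunction of three exact comparisons — identical `nameComplete`,
identical `@id`, identical occurrence identifier — and is symmetric by
construction. Deliberate choices:

* Name comparison is case-sensitive and collapses internal whitespace
  runs (guarding against artifacts of Newick/JSON round-trips), nothing
  more; no synonymy, no fuzzy matching, no authority comparison, and
  nomenclatural codes need not agree.
* IRIs are compared verbatim, with no normalization.
* Specimen identifiers: an explicit `occurrenceID` always wins;
  otherwise the Darwin Core Triplet parts are joined with `:`, omitting
  empty leading parts, so institution + catalog yields `UC:Wall 2527,
  Fiji`. The triplet convention fixes the parts but not a single
  serialization; the join rule here is documented so that matching is
  internally consistent.
* Name parsing accepts uninomials, binomials and trinomials with an
  optional trailing authority. The trinomial's third epithet is kept
  only inside `nameComplete` (the format defines no infraspecific
  field).

## Document validation

Validation is code-driven and produces structured findings
(JSON path, severity, message). Hard errors: missing `@context`,
missing `newick`, unparseable Newick, missing `definition`, specifier
arity violations, `expectedResolution` keys naming phylogenies absent
from the document, duplicate ids. Unknown fields are warnings only —
JSON-LD contexts tolerate extra terms. An `additionalNodeProperties`
key matching no node label warns rather than errors, since the tree may
legitimately evolve ahead of its annotations.

Arity rules: minimum clade needs ≥ 2 internal specifiers, or exactly one
internal plus ≥ 1 external (that arity is accepted for both clade types
and compiled with the maximum-clade expression family, the only form
available for it); maximum clade needs ≥ 1 internal and ≥ 1 external;
apomorphy-based needs exactly one internal, no externals, and an
apomorphy.

Id minting assigns `#phylogeny<i>` / `#phyloref<i>` fragments by
document order, never touches existing ids (idempotent), and fails on
collisions. Node individuals are minted at conversion time as
`<phylogeny id>_node<i>` with *i* the preorder index, so output is
deterministic for a fixed input.

## Ontology output

Conversion adds the `owl:Ontology` type and the two phyloreferencing
application-ontology imports, represents every tree node as a CDAO node
individual with `has_Child` and (transitive) `has_Descendant` links plus
`represents_TU` annotations, and attaches each phyloreference's
generated component classes as subclasses with `equivalentClass`
expressions. Software-only fields (specifier lists,
`expectedResolution`, `additionalNodeProperties`) are consumed, not
emitted. Apomorphy-based definitions convert with their metadata but
skip expression generation, recording an "unsupported" finding.

The JSON-LD structure follows the standard term mappings (CDAO, TDWG
taxon concept/name, Darwin Core, the phyloreferencing ontology);
byte-level equality with any other serializer is explicitly not a goal.
The optional N-Triples export inlines a local prefix map (with a
fallback vocabulary for unmapped terms) so it works without network
access; it is a faithful graph of this structure, best-effort by design.

## Expression generation

The node-relation vocabulary: `includes_TU(t)` holds at a node that
represents *t* or has a strict descendant that does; `excludes_TU(t)`
holds where a sibling or a descendant of a sibling represents *t*;
`excludes_lineage_to(E)` generalizes the latter to any expression *E*;
`has_Child`/`has_Ancestor` are one step down / any strict steps up.
"Descendant" and "ancestor" are strict wherever composed with sibling
steps; `includes_TU` alone is reflexive — this asymmetry is taken
literally from the property definitions.

**Two internals.** `has_Child some (includes_TU some i₁ and excludes_TU
some i₂)` is satisfied at a node *p* iff some child of *p* leads to i₁
while a sibling subtree of that child leads to i₂ — i.e. iff
*p* = MRCA(i₁, i₂). This holds on any rooted tree including polytomies,
and is symmetric in the specifiers.

**Minimum clade, n internals.** One component per unordered pair
{i, j}: the pair's MRCA expression conjoined with `includes_TU some k`
for every other internal k — hence exactly n(n−1)/2 components.
Correctness argument: a node satisfying the component is MRCA(i, j) and
covers all internals, so it lies both at-or-below and at-or-above the
MRCA *m* of the full set (MRCA(i, j) descends from any common ancestor
of i and j, and a node covering all internals is an ancestor-or-self of
*m*), forcing it to equal *m*; conversely the leaves under *m* split
across ≥ 2 child subtrees, so some pair {i, j} straddles them and its
component is satisfied at *m*. The union of components is therefore
exactly {m} on every topology. The recursive formulation this replaces
produces the same printed component count but its published stop
condition halts every branch immediately after the first selection,
which generates n, not n(n−1)/2, expressions; since only the count law
and the MRCA semantics are contracted, the pair-anchored family — built
solely from the same published building blocks — is used instead.
Structurally identical components are deduplicated on a canonical,
intersection-order-insensitive form before counting.

**Maximum clade.** One component per external *e*: the intersection of
`includes_TU` over all internals, `excludes_TU some e`, and `has_Ancestor
some (excludes_TU some e′)` for every other external e′. With a single
external this is provably exact: the satisfied node is the unique
ancestor-or-self of the internals that is *e*-free while its parent is
not. With two or more externals that branch off at the same split the
published construction can leave every component unsatisfied (no
ancestor then excludes the *other* external through a sibling); the
implementation reproduces this behavior faithfully and reports
"unresolved" rather than patching the semantics, so the edge case stays
observable.

## Resolution

The evaluator computes satisfaction sets bottom-up over precomputed
descendant-or-self and sibling-lineage indices; an independent per-node
truth-table oracle (recursion straight from the relation definitions,
sharing no code) agrees with it exhaustively on every topology with up
to five leaves across a varied expression zoo. Resolution returns node
*sets* — uniqueness is reported (`resolved-unique` vs
`resolved-multiple`), never forced — and keeps per-component sets so
each emitted expression's behavior remains visible. Specifier-to-node
matching runs the full three-facet matcher over each node's complete
unit set, so names, IRIs and specimen identifiers are all eligible.

The reference-tree algorithm mirrors the two-step process used against
synthesis trees: translate each specifier's name through a name index
(leaf labels only by default; a flag adds internal labels), skipping the
phyloreference if any name is missing; then return the internals' MRCA
for a minimum clade, or the earliest (most rootward) external-excluding
ancestor for a maximum clade.

## Topology enumeration and the sweep

Enumeration inserts leaves A…F one at a time into every edge and every
internal node of every smaller topology, deduplicating on a canonical
sorted-nested-tuple form. This is provably exhaustive for rooted trees
with out-degrees ≥ 2 and reproduces the census 1, 4, 26, 236, 2,752
(totals) and 1, 3, 15, 105, 945 (strictly bifurcating, the (2n−3)!!
series) for n = 2…6. Canonical-form uniqueness replaces a pairwise
Robinson–Foulds check; the suite still runs an independent
dendropy-based RF check at n = 4 as confirmation.

The labeling scheme writes every node as `N<descendant leaf letters>_
<letters of leaves under or equal to any sibling>`, both parts sorted; a
sibling leaf contributes its own letter, and the underscore is emitted
even for the root (whose sibling part is empty). The expected minimum
clade is the label with the fewest leaves starting `NAB`; the expected
maximum clade the fewest-leaf label matching `NA.*_.*C.*`. "Fewest
leaves" (the length of the part before the underscore) is the operative
ordering: plain string length ties it on shapes like `((A,B),(C,D))`,
where `NAB_CD` and `NABCD_` are equally long and lexicographic order
would pick the wrong node; two distinct candidates with the same leaf
count cannot exist because clades sharing leaf A are nested. A final
lexicographic key is kept as a formal tie-break only.

Sweep documents embed each scheme-labeled topology as a quoted-label
Newick string, associate each leaf with its single-letter taxonomic unit
via `additionalNodeProperties` (scheme labels themselves are not parsed
as taxon names), and name the two test phyloreferences after their
expected nodes. A topology where the expected node does not exist (the
maximum clade on the 2-leaf tree, which has no C) must come back
unresolved; the aggregate pass fraction counts only checks whose
expected node exists. All sizes n = 2…6 run in a few seconds total.

## What the tests show — and what they do not

The sweep and oracle-equivalence suites are exhaustive over *topologies*
(≤ 6 and ≤ 5 leaves respectively) with single-letter leaf names mapped
one-to-one onto specifiers. They therefore establish correctness of the
expression semantics on every branching structure in that range,
including polytomies. They do not exercise: larger trees (no new
structural cases arise, but no exhaustive claim is made), messy
real-world labels (covered separately by the name parser and the
crocodylian example, not exhaustively), duplicate taxa on one tree
(resolution then legitimately returns multiple nodes), reticulate
networks (rejected at parse time), or OWL reasoner behavior (the
evaluator replaces the reasoner; the ontology output is structured for
one but not executed against one here).

## Known limitations

* Apomorphy-based definitions are carried as data only; no logic
  expressions are generated for them.
* Multi-external maximum clades can be unresolvable on topologies where
  all externals attach at one split (see above) — reported, not masked.
* The `@context` IRI is emitted, not dereferenced; validation is
  structural, not schema-driven, and the N-Triples export is
  best-effort.
* Name matching is exact; curators must annotate taxon substitutions
  explicitly rather than rely on fuzzy matching.
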