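# phyx — computable phylogenetic clade definitions

Linnaean names are text strings whose meaning drifts; phylogenetic
(clade) definitions are anchored to trees and have semantics a machine
can evaluate. This package implements the **Phyloreference Exchange
Format (Phyx)** — a JSON-LD data standard in which digitized clade
definitions ("phyloreferences") travel together with the reference
phylogenies they are tested against — and everything needed to *compute*
with such definitions:

* a rooted-tree model with a Newick reader/writer that preserves
  polytomies, quoted labels and internal node names;
* taxonomic units (taxon concepts, specimens, opaque IRIs) with the
  three standard matchers (`nameComplete`, `@id`, occurrence ID);
* document parsing, structured validation findings, id minting, and
  conversion to ontology-structured JSON-LD (node individuals with
  CDAO child/descendant links, OWL-style component class expressions);
* generation of node-class expressions from a definition's specifiers,
  and a direct tree-based evaluator for them (no reasoner required);
* an exhaustive topology sweep verifying correct resolution on **every**
  rooted topology with up to six labeled leaves.

It is aimed at developers of biodiversity-informatics tools and at
anyone who wants to check, resolve, or systematically test digitized
clade definitions.

## The model

A phyloreference is one of:

* **minimum clade** — the smallest clade originating with the MRCA of
  internal specifiers i₁…iₙ;
* **maximum clade** — the largest clade containing the internal
  specifier(s) but excluding every external specifier;
* **apomorphy-based** — the clade arising with the first appearance of a
  trait (recorded in the format; not convertible to logic expressions).

Definitions are compiled to expressions over five node-level relations —
`includes_TU`, `excludes_TU`, `excludes_lineage_to`, `has_Child`,
`has_Ancestor` — plus intersection. The two-specifier building block

```
has_Child some (includes_TU some i₁ and excludes_TU some i₂)
```

is satisfied at exactly MRCA(i₁, i₂) on any rooted tree, polytomies
included. A minimum clade with *n* internals emits one component per
specifier pair — *n(n−1)/2* components, since disjunction is outside the
OWL2 EL profile — and a maximum clade one component per external
specifier; a node satisfying any component resolves the phyloreference.

## Worked example

The bundled archosaur phylogeny carries named internal clades, and the
maximum-clade definition of **Alligatoroidea** — *Alligator
mississippiensis* and all crocodylians closer to it than to *Crocodylus
niloticus* or *Gavialis gangeticus*:

```python
import json
from phyx import load_phyx, resolve_document
from phyx.fixtures import crocodylia_document

doc = load_phyx(json.dumps(crocodylia_document()))
result = resolve_document(doc)[0]
print(result.status.value, result.resolved_labels, result.expectation_met)
```

prints

```
resolved-unique ['Alligatoroidea'] True
```

— the definition's two component expressions (one per external
specifier) select exactly the internal node labeled "Alligatoroidea",
matching the curator's recorded expectation. Running
`python examples/04_topology_sweep.py` exercises the exhaustive sweep:

```
n=2:     1 topologies (   1 bifurcating,     0 multifurcating) -> 1/1 checks passed (100%)
n=3:     4 topologies (   3 bifurcating,     1 multifurcating) -> 8/8 checks passed (100%)
n=4:    26 topologies (  15 bifurcating,    11 multifurcating) -> 52/52 checks passed (100%)
n=5:   236 topologies ( 105 bifurcating,   131 multifurcating) -> 472/472 checks passed (100%)
n=6:  2752 topologies ( 945 bifurcating,  1807 multifurcating) -> 5504/5504 checks passed (100%)
```

Every node of every topology is labeled by a scheme encoding its
descendant and sibling leaves (the node above {A,B} with siblings
{C,D} is `NAB_CD`), which predicts where the two test definitions —
minimum clade of {A,B}, maximum clade including A but excluding C —
must resolve; 100% means resolution is exact on every possible
branching structure.

The `examples/` scripts each demonstrate one capability; the `phyx`
command-line tool (`validate`, `convert`, `resolve`, `sweep`,
`fixtures`) wraps the same library functions for shell use, e.g.
`phyx resolve my.phyx.json --write-table results.tsv`.

## Layout

| Path | Contents |
| --- | --- |
| `src/phyx/tree_model.py` | rooted trees, Newick/Nexus I/O, node relations |
| `src/phyx/taxonomic_units.py` | taxon names, specimens, matchers |
| `src/phyx/phyx_document.py` | document model, validation, ontology output |
| `src/phyx/clade_expressions.py` | specifier → expression generation |
| `src/phyx/resolution.py` | expression evaluation, clade oracles |
| `src/phyx/topology_sweep.py` | enumeration, labeling scheme, sweep |
| `src/phyx/cli.py`, `src/phyx/fixtures.py` | shell tool, example corpus |
| `docs/methods.md` | models, algorithms, design choices, limitations |
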