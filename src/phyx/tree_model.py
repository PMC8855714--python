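"""Rooted, possibly multifurcating trees and their Newick serialization.

Phylogenies travel inside Phyx documents as Newick strings, so this module
provides the parser, the writer, and the purely structural node relations
(parent, siblings, ancestors, descendants) that the clade-resolution
semantics are built on.  Branch lengths are parsed for fidelity but are
never consulted by resolution, which is purely topological.

Dialect notes
-------------
* Labels may be single-quoted; a doubled quote inside a quoted label
  (``'it''s'``) encodes a literal quote character.
* In *unquoted* labels, underscores are read as spaces (the classic Newick
  convention), so a leaf written ``Alligator_mississippiensis`` carries the
  label ``"Alligator mississippiensis"``.
* Square-bracket comments are skipped.
* Polytomies and unifurcations are preserved exactly as written.
* Extended-Newick reticulation tags (``#H1``) are rejected with
  :class:`UnsupportedNewickFeature` — phylogenetic networks are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set

__all__ = [
    "TreeNode",
    "RootedTree",
    "NewickParseError",
    "UnsupportedNewickFeature",
    "NodeNotInTree",
    "parse_newick",
    "write_newick",
    "write_nexus",
    "siblings",
    "descendants",
    "ancestors",
    "mrca",
]


class NewickParseError(ValueError):
    """Malformed Newick input; ``position`` is the 0-based character offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class UnsupportedNewickFeature(ValueError):
    """Syntactically valid input using a feature outside this dialect."""


class NodeNotInTree(KeyError):
    """A node was passed together with a tree it does not belong to."""


@dataclass(eq=False)
class TreeNode:
    """One node of a rooted tree.

    ``node_id`` is assigned by the owning :class:`RootedTree` and is unique
    within it.  Equality is identity: two structurally identical nodes in
    different trees are distinct objects.
    """

    label: Optional[str] = None
    children: List["TreeNode"] = field(default_factory=list)
    branch_length: Optional[float] = None
    node_id: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal of this node's subtree (self first)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class RootedTree:
    """A rooted tree with a node registry and parent index.

    Node ids ``n0, n1, ...`` are assigned in preorder, so they are stable
    for a given topology and child order.
    """

    def __init__(self, root: TreeNode, source_newick: Optional[str] = None):
        self.root = root
        self.source_newick = source_newick
        self._parent: Dict[int, TreeNode] = {}
        self._by_id: Dict[str, TreeNode] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._parent.clear()
        self._by_id.clear()
        for i, node in enumerate(self.root.walk()):
            node.node_id = f"n{i}"
            self._by_id[node.node_id] = node
            for child in node.children:
                self._parent[id(child)] = node

    # -- membership and lookup -------------------------------------------

    def __contains__(self, node: TreeNode) -> bool:
        return node.node_id is not None and self._by_id.get(node.node_id) is node

    def __len__(self) -> int:
        return len(self._by_id)

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise NodeNotInTree(f"no node with id {node_id!r}") from None

    def parent(self, node: TreeNode) -> Optional[TreeNode]:
        self._require(node)
        return self._parent.get(id(node))

    def _require(self, node: TreeNode) -> None:
        if node not in self:
            raise NodeNotInTree(
                f"node {node.label!r} (id={node.node_id!r}) is not part of this tree"
            )

    # -- structural equality ---------------------------------------------

    def structurally_equal(self, other: "RootedTree") -> bool:
        """Same labels and same child multisets, recursively."""
        return _canonical(self.root) == _canonical(other.root)


def _canonical(node: TreeNode):
    if node.is_leaf:
        return (node.label,)
    return (node.label, tuple(sorted((_canonical(c) for c in node.children), key=repr)))


# ---------------------------------------------------------------------------
# Newick reading
# ---------------------------------------------------------------------------

_UNQUOTED_TERMINATORS = set("(),:;[]'")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> NewickParseError:
        return NewickParseError(message, self.pos)

    def peek(self) -> Optional[str]:
        self._skip_space_and_comments()
        return self.text[self.pos] if self.pos < len(self.text) else None

    def _skip_space_and_comments(self) -> None:
        while self.pos < len(self.text):
            c = self.text[self.pos]
            if c.isspace():
                self.pos += 1
            elif c == "[":
                end = self.text.find("]", self.pos)
                if end == -1:
                    raise self.error("unterminated '[' comment")
                self.pos = end + 1
            else:
                return

    def parse(self) -> TreeNode:
        root = self.parse_clade()
        c = self.peek()
        if c == ";":
            self.pos += 1
        elif c is None:
            warnings.warn("Newick string missing terminal ';' — auto-appended")
        else:
            raise self.error(f"unexpected character {c!r} after complete tree")
        if self.peek() is not None:
            raise self.error("trailing content after terminal ';'")
        return root

    def parse_clade(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                c = self.peek()
                if c in (",", ")"):
                    raise self.error("empty clade element (dangling comma or '()')")
                node.children.append(self.parse_clade())
                c = self.peek()
                if c == ",":
                    self.pos += 1
                elif c == ")":
                    self.pos += 1
                    break
                elif c is None:
                    raise self.error("unbalanced '(': input ended inside a clade")
                else:
                    raise self.error(
                        f"expected ',' or ')', found {c!r} — unbalanced parentheses?")
        node.label = self.parse_label()
        if self.peek() == ":":
            self.pos += 1
            node.branch_length = self.parse_number()
        return node

    def parse_label(self) -> Optional[str]:
        c = self.peek()
        if c is None:
            return None
        if c == "'":
            return self.parse_quoted_label()
        if c in _UNQUOTED_TERMINATORS:
            # ')' ',' ':' ';' here mean the node is simply unlabeled;
            # structural errors are caught by the clade/tree parsers
            return None
        start = self.pos
        while self.pos < len(self.text) and not (
            self.text[self.pos] in _UNQUOTED_TERMINATORS or self.text[self.pos].isspace()
        ):
            self.pos += 1
        raw = self.text[start : self.pos]
        if "#" in raw:
            raise UnsupportedNewickFeature(
                f"extended-Newick reticulation tag in label {raw!r} "
                f"(at character {start}); phylogenetic networks are not supported"
            )
        # classic convention: underscores in unquoted labels are spaces
        return raw.replace("_", " ")

    def parse_quoted_label(self) -> str:
        assert self.text[self.pos] == "'"
        self.pos += 1
        out: List[str] = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            c = self.text[self.pos]
            if c == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    return "".join(out)
            else:
                out.append(c)
                self.pos += 1

    def parse_number(self) -> float:
        self._skip_space_and_comments()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isdigit() or self.text[self.pos] in "+-.eE"
        ):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            value = float(token)
        except ValueError:
            raise NewickParseError(f"invalid branch length {token!r}", start) from None
        if value < 0:
            raise NewickParseError(f"negative branch length {token!r}", start)
        return value


def parse_newick(newick: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    A missing terminal ``;`` is tolerated with a warning.  Malformed input
    raises :class:`NewickParseError` carrying the character position;
    extended-Newick ``#H`` reticulation tags raise
    :class:`UnsupportedNewickFeature`.
    """
    if not newick or not newick.strip():
        raise NewickParseError("empty Newick string", 0)
    root = _Parser(newick).parse()
    return RootedTree(root, source_newick=newick)


# ---------------------------------------------------------------------------
# Newick / Nexus writing
# ---------------------------------------------------------------------------

# The underscore is included because an unquoted underscore would be read
# back as a space, breaking round-trips.
_NEEDS_QUOTING = set(" ()[],:;'_")


def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if label == "" or any(c in _NEEDS_QUOTING or c.isspace() for c in label) or "#" in label:
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: TreeNode, parts: List[str], with_lengths: bool) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _write_node(child, parts, with_lengths)
        parts.append(")")
    parts.append(_format_label(node.label))
    if with_lengths and node.branch_length is not None:
        parts.append(f":{node.branch_length:g}")


def write_newick(tree: RootedTree, include_branch_lengths: bool = True) -> str:
    """Serialize to Newick such that ``parse(write(t))`` equals ``t``."""
    parts: List[str] = []
    _write_node(tree.root, parts, include_branch_lengths)
    parts.append(";")
    return "".join(parts)


def write_nexus(trees: List[RootedTree], names: Optional[List[str]] = None) -> str:
    """Render trees as a minimal Nexus TREES block (one ``TREE`` line each)."""
    if names is None:
        names = [f"tree{i + 1}" for i in range(len(trees))]
    lines = ["#NEXUS", "", "BEGIN TREES;"]
    for name, tree in zip(names, trees):
        lines.append(f"    TREE {name} = [&R] {write_newick(tree)}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Structural relations
# ---------------------------------------------------------------------------

def siblings(node: TreeNode, tree: RootedTree) -> Set[TreeNode]:
    """All other children of ``node``'s parent; empty for the root."""
    parent = tree.parent(node)
    if parent is None:
        return set()
    return {c for c in parent.children if c is not node}


def descendants(node: TreeNode, tree: RootedTree) -> Set[TreeNode]:
    """Strict descendants of ``node`` (the node itself is excluded)."""
    tree._require(node)
    out: Set[TreeNode] = set(node.walk())
    out.discard(node)
    return out


def ancestors(node: TreeNode, tree: RootedTree) -> Set[TreeNode]:
    """Strict ancestors of ``node``, nearest first excluded from nothing."""
    tree._require(node)
    out: Set[TreeNode] = set()
    current = tree.parent(node)
    while current is not None:
        out.add(current)
        current = tree.parent(current)
    return out


def mrca(nodes: List[TreeNode], tree: RootedTree) -> TreeNode:
    """Most recent common ancestor of ``nodes`` (ancestor-or-self)."""
    if not nodes:
        raise ValueError("mrca() of an empty node set is undefined")
    paths = []
    for node in nodes:
        tree._require(node)
        path = [node]
        current = tree.parent(node)
        while current is not None:
            path.append(current)
            current = tree.parent(current)
        paths.append(list(reversed(path)))  # root .. node
    answer = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            answer = candidate
        else:
            break
    return answer
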