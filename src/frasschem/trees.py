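"""Rooted binary dendrograms with merge heights, plus newick round-tripping.

A dendrogram node carries the height at which its two children merged
(leaves sit at height 0), so the tree is ultrametric by construction when
produced by average-linkage clustering.  Newick branch lengths are the
height differences between parent and child.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterator, Sequence

import dendropy


class NewickError(ValueError):
    """Raised for malformed or unsupported newick input."""


class Node:
    """A node of a rooted binary dendrogram.

    Leaves have a ``name`` and height 0; internal nodes have exactly two
    children and a merge ``height`` no smaller than either child's.
    """

    __slots__ = ("name", "height", "children")

    def __init__(self, name: str | None, height: float, children: tuple = ()):
        if children and len(children) != 2:
            raise ValueError("internal nodes must have exactly two children")
        self.name = name
        self.height = float(height)
        self.children = tuple(children)

    # -- constructors -------------------------------------------------
    @classmethod
    def leaf(cls, name: str) -> "Node":
        return cls(name, 0.0, ())

    @classmethod
    def merge(cls, left: "Node", right: "Node", height: float) -> "Node":
        return cls(None, height, (left, right))

    # -- structure ----------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.iter_leaves()

    def leaf_names(self) -> list[str]:
        """Leaf labels in left-to-right display order."""
        return [l.name for l in self.iter_leaves()]

    @property
    def size(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    def min_leaf(self) -> str:
        return min(self.leaf_names())

    def ladderize(self) -> "Node":
        """Return a copy with, at every node, the larger subtree last.

        Ties are broken by placing the subtree with the lexicographically
        smaller minimal leaf name first, which makes the ordering fully
        deterministic.
        """
        if self.is_leaf:
            return self
        kids = [c.ladderize() for c in self.children]
        kids.sort(key=lambda c: (c.size, c.min_leaf()))
        return Node(self.name, self.height, tuple(kids))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.name!r})"
        return f"Node(h={self.height:g}, n={self.size})"


def is_ultrametric(root: Node, tol: float = 1e-9) -> bool:
    """Check the three-point condition via monotone heights.

    For a merge-height tree, ultrametricity is equivalent to heights being
    nondecreasing from every child to its parent.
    """
    if root.is_leaf:
        return True
    return all(
        c.height <= root.height + tol and is_ultrametric(c, tol)
        for c in root.children
    )


# ---------------------------------------------------------------------------
# newick serialization
# ---------------------------------------------------------------------------

def to_newick(root: Node) -> str:
    """Serialize a dendrogram to a newick string with branch lengths."""

    def rec(node: Node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.name)}:{bl:.12g}"
        inner = ",".join(rec(c, node.height) for c in node.children)
        return f"({inner}):{bl:.12g}"

    if root.is_leaf:
        return f"{_quote(root.name)}:0;"
    inner = ",".join(rec(c, root.height) for c in root.children)
    return f"({inner}):0;"


def _quote(name: str | None) -> str:
    name = name or ""
    if any(ch in name for ch in "(),:;[] '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(root: Node, path: str | Path) -> None:
    Path(path).write_text(to_newick(root) + "\n")


def from_newick(text: str) -> Node:
    """Parse a newick string into a dendrogram.

    Branch lengths are required on internal edges of multi-leaf trees;
    node heights are reconstructed as the maximal leaf-ward path length,
    which recovers merge heights exactly for ultrametric input.
    """
    opens, closes = text.count("("), text.count(")")
    if opens != closes:
        raise NewickError(
            f"unbalanced parentheses: {opens} '(' vs {closes} ')' "
            f"(first mismatch near position {_mismatch_pos(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")

    def convert(nd) -> Node:
        kids = nd.child_nodes()
        if not kids:
            return Node.leaf(nd.taxon.label)
        if len(kids) == 1:  # collapse unifurcations (e.g. rooted root edge)
            return convert(kids[0])
        if len(kids) > 2:
            raise NewickError("dendrogram must be binary")
        conv = []
        for k in kids:
            child = convert(k)
            bl = k.edge.length if k.edge.length is not None else 0.0
            conv.append((child, bl))
        height = max(c.height + bl for c, bl in conv)
        return Node(None, height, tuple(c for c, _ in conv))

    return convert(tree.seed_node)


def _mismatch_pos(text: str) -> int:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def read_newick(path: str | Path) -> Node:
    return from_newick(Path(path).read_text())
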