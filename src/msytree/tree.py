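"""Rooted haplogroup trees with marker-annotated branches.

The tree models the MSY genealogy at haplogroup resolution.  Every node
stands for a clade; the branch subtending a node carries the set of
markers whose derived allele is shared by exactly the chromosomes below
(markers sharing a branch are *phylogenetically equivalent*).  The root
state is ancestral at every marker.

Nodes may additionally carry:

* ``samples`` — panel chromosomes whose terminal resolution is this node.
  A sample resting at an *internal* node is a paragroup resident: derived
  at the node's defining markers, ancestral or untyped at every child's.
* ``token`` — the terminal-haplogroup token of a backbone leaf.  It stays
  on the node when refinement grows children below a former leaf, so
  clade signatures remain comparable between backbone and refined trees.
* ``putative`` — branch drawn without a derived positive control
  (rendered dashed in field figures).
* ``collapsed`` — number of known sub-branches not represented (drawn as
  a triangle); such subtrees are excluded from refinement counting.

Serialization is Newick with ``[&key=value,...]`` comment annotations;
the writer is deterministic so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import io
import re
from typing import Callable, Iterator, Optional, Union

import dendropy

__all__ = ["HaplogroupNode", "HaplogroupTree", "TreeError", "read_newick", "write_newick"]


class TreeError(ValueError):
    pass


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9.\-]+$")


class HaplogroupNode:
    __slots__ = (
        "name",
        "lineage",
        "markers",
        "children",
        "samples",
        "putative",
        "collapsed",
        "token",
        "origin",
    )

    def __init__(
        self,
        name: Optional[str] = None,
        markers: Optional[list[str]] = None,
        children: Optional[list["HaplogroupNode"]] = None,
        samples: Optional[list[str]] = None,
        putative: bool = False,
        collapsed: int = 0,
        token: Optional[str] = None,
        lineage: Optional[str] = None,
        origin: str = "backbone",
    ) -> None:
        self.name = name
        self.lineage = lineage
        self.markers = list(markers or [])
        self.children = list(children or [])
        self.samples = list(samples or [])
        self.putative = putative
        self.collapsed = collapsed
        self.token = token
        self.origin = origin

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"HaplogroupNode({self.name!r}, markers={self.markers},"
            f" samples={self.samples}, children={len(self.children)})"
        )


class HaplogroupTree:
    """A rooted tree of :class:`HaplogroupNode`; the root is all-ancestral."""

    def __init__(self, root: HaplogroupNode) -> None:
        self.root = root

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> Iterator[HaplogroupNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[HaplogroupNode]:
        out: list[HaplogroupNode] = []

        def walk(n: HaplogroupNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return iter(out)

    def parent_map(self) -> dict[int, Optional[HaplogroupNode]]:
        pm: dict[int, Optional[HaplogroupNode]] = {id(self.root): None}
        for node in self.preorder():
            for c in node.children:
                pm[id(c)] = node
        return pm

    def find(self, name: str) -> HaplogroupNode:
        for node in self.preorder():
            if node.name == name:
                return node
        raise TreeError(f"no node named {name!r}")

    def find_marker_branch(self, marker: str) -> HaplogroupNode:
        for node in self.preorder():
            if marker in node.markers:
                return node
        raise TreeError(f"marker {marker!r} is on no branch")

    # -- clade content -------------------------------------------------------

    def clade_samples(self, node: HaplogroupNode) -> frozenset[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            out.update(n.samples)
            stack.extend(n.children)
        return frozenset(out)

    def signature(self, node: HaplogroupNode) -> frozenset[str]:
        """Terminal content of the clade: sample ids plus leaf tokens.

        Tokens persist when a backbone leaf becomes internal, so a node of
        the refined tree matches its backbone counterpart iff it subtends
        the same terminal material.
        """
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            out.update(n.samples)
            if n.token:
                out.add(n.token)
            stack.extend(n.children)
        return frozenset(out)

    def all_markers(self) -> list[str]:
        out: list[str] = []
        for node in self.preorder():
            out.extend(node.markers)
        return out

    def sample_positions(self) -> dict[str, HaplogroupNode]:
        pos: dict[str, HaplogroupNode] = {}
        for node in self.preorder():
            for s in node.samples:
                if s in pos:
                    raise TreeError(f"sample {s!r} attached twice")
                pos[s] = node
        return pos

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            for m in node.markers:
                if m in seen:
                    raise TreeError(f"marker {m!r} appears on more than one branch")
                seen.add(m)
        for node in self.preorder():
            for c in node.children:
                if not c.is_leaf() and not c.markers and not c.putative:
                    raise TreeError(
                        f"internal node {c.name!r} has no markers and is not putative"
                    )

    # -- copying -------------------------------------------------------------

    def copy(self) -> "HaplogroupTree":
        def clone(n: HaplogroupNode) -> HaplogroupNode:
            return HaplogroupNode(
                name=n.name,
                markers=list(n.markers),
                children=[clone(c) for c in n.children],
                samples=list(n.samples),
                putative=n.putative,
                collapsed=n.collapsed,
                token=n.token,
                lineage=n.lineage,
                origin=n.origin,
            )

        return HaplogroupTree(clone(self.root))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplogroupTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    # -- topology comparisons ------------------------------------------------

    def clade_set(self, content: str = "samples") -> frozenset[frozenset[str]]:
        """Set of non-trivial clades as sample sets (or full signatures)."""
        fn: Callable[[HaplogroupNode], frozenset[str]]
        fn = self.clade_samples if content == "samples" else self.signature
        out = set()
        for node in self.preorder():
            sig = fn(node)
            if sig:
                out.add(sig)
        return frozenset(out)


# ---------------------------------------------------------------------------
# Newick serialization


def _quote(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _annotation(node: HaplogroupNode) -> str:
    parts: list[str] = []
    if node.markers:
        parts.append("markers=" + "|".join(node.markers))
    if node.samples:
        parts.append("samples=" + "|".join(node.samples))
    if node.token is not None:
        parts.append("token=" + node.token)
    if node.lineage is not None:
        parts.append("lineage=" + node.lineage)
    if node.putative:
        parts.append("putative=1")
    if node.collapsed:
        parts.append(f"collapsed={node.collapsed}")
    if node.origin != "backbone":
        parts.append("origin=" + node.origin)
    if not parts:
        return ""
    return "[&" + ",".join(parts) + "]"


def write_newick(tree: HaplogroupTree) -> str:
    def render(node: HaplogroupNode) -> str:
        inner = ""
        if node.children:
            inner = "(" + ",".join(render(c) for c in node.children) + ")"
        label = _quote(node.name) if node.name else ""
        return inner + label + _annotation(node)

    return render(tree.root) + ";\n"


def _from_dendropy(dnode: "dendropy.Node") -> HaplogroupNode:
    ann = dnode.annotations.values_as_dict()
    label = dnode.taxon.label if dnode.taxon else dnode.label
    node = HaplogroupNode(
        name=label or None,
        markers=ann.get("markers", "").split("|") if ann.get("markers") else [],
        samples=ann.get("samples", "").split("|") if ann.get("samples") else [],
        token=ann.get("token"),
        lineage=ann.get("lineage"),
        putative=ann.get("putative") == "1",
        collapsed=int(ann.get("collapsed", 0)),
        origin=ann.get("origin", "backbone"),
    )
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def read_newick(source: Union[str, io.TextIOBase]) -> HaplogroupTree:
    """Parse annotated Newick (structure via dendropy, payload via codec)."""
    text = source if isinstance(source, str) else source.read()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    return HaplogroupTree(_from_dendropy(dtree.seed_node))
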