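"""Haplogroup naming and backbone-vs-refined tree comparison.

The field uses two naming systems side by side.  *Mutation-based* names
(``A-V218``, ``C-V20``) combine the major-clade letter with a defining
marker of the branch and never change as the tree grows.  *Lineage-based*
labels (``A3b1``, ``C7``) encode the path from the clade root and are
extended with the next free letter/digit when a sibling is added.  This
module assigns both to newly created nodes (backbone names are preserved
untouched), renders paragroups with a trailing ``*``, and computes the
refinement report: which haplogroups and paragroups are new relative to
the backbone, which polytomies were resolved, which markers moved, and
which equivalence classes merge newly typed markers with published ones.

Counting conventions (stated once, applied everywhere): a *new
haplogroup* is a marker-defined clade of the refined tree whose terminal
content matches no backbone clade, excluding nodes created by
repositioning a marker the backbone already carried (those are the
polytomy resolutions, reported separately).  A *new paragroup* is a
chromosome left resting at an internal node where the backbone did not
already leave it.  Collapsed subtrees (drawn as triangles) never count.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .tree import HaplogroupNode, HaplogroupTree, TreeError

__all__ = [
    "assign_names",
    "mutation_based_name",
    "paragroup_names",
    "RefinementReport",
    "diff_trees",
]


def _clade_letter(tree: HaplogroupTree, node: HaplogroupNode) -> str:
    """Major-clade letter: from leaf tokens below, else the nearest named
    ancestor, else ``Y`` (the whole tree)."""
    tokens = tree.signature(node) & _token_universe(tree)
    letters = {t[0] for t in tokens if t[0].isalpha() and t[0].isupper()}
    if len(letters) == 1:
        return next(iter(letters))
    pm = tree.parent_map()
    cur = pm.get(id(node))
    while cur is not None:
        if cur.name and cur.name[0].isalpha() and cur.name[0].isupper():
            return cur.name[0]
        cur = pm.get(id(cur))
    return "Y"


def mutation_based_name(tree: HaplogroupTree, node: HaplogroupNode) -> Optional[str]:
    """``<letter>-<lexicographically first marker>``, or None if unnameable."""
    if not node.markers:
        return None
    return f"{_clade_letter(tree, node)}-{min(node.markers)}"


_ENDS_DIGIT = re.compile(r"\d$")


def _next_lineage(parent: HaplogroupNode) -> Optional[str]:
    """Next free lineage label under ``parent`` (letters and digits alternate)."""
    base = parent.lineage or parent.name
    if not base:
        return None
    want_digit = not _ENDS_DIGIT.search(base)
    taken = set()
    for c in parent.children:
        lab = c.lineage or (c.name if c.name and c.name.startswith(base) else None)
        if lab and lab.startswith(base) and len(lab) > len(base):
            taken.add(lab[len(base)])
    if want_digit:
        for i in range(1, 100):
            if str(i) not in taken:
                return f"{base}{i}"
    else:
        for o in range(ord("a"), ord("z") + 1):
            if chr(o) not in taken:
                return f"{base}{chr(o)}"
    return None


def assign_names(
    tree: HaplogroupTree, in_place: bool = True
) -> tuple[HaplogroupTree, dict[str, HaplogroupNode], list[str]]:
    """Name every unnamed marker-bearing or putative branch.

    Backbone names are preserved.  New nodes get their mutation-based
    name; new *terminal* branches additionally get the next free
    lineage-based label when the parent carries one (that is how the
    seventh C sub-branch becomes ``C7``).  A putative branch with no
    marker gets a placeholder name and a warning.  Returns the (possibly
    copied) tree, a name -> node map, and the warnings.
    """
    out = tree if in_place else tree.copy()
    warnings: list[str] = []
    used = {n.name for n in out.preorder() if n.name}
    pm = out.parent_map()
    counter = 0
    for node in out.preorder():
        if node.name or node is out.root:
            continue
        if not node.markers and not node.children and node.samples:
            continue  # bare chromosome holder, not a haplogroup
        name = mutation_based_name(out, node)
        if name is None:
            counter += 1
            name = f"{_clade_letter(out, node)}-?{counter}"
            warnings.append(
                f"unnameable branch (putative, no marker): placeholder {name}"
            )
        while name in used:
            name += "'"
        node.name = name
        used.add(name)
        parent = pm[id(node)]
        # lineage labels only for new terminal branches; nodes inserted
        # above existing structure keep the frozen mutation-based name
        if node.lineage is None and parent is not None and not node.children:
            node.lineage = _next_lineage(parent)
    name_map = {n.name: n for n in out.preorder() if n.name}
    return out, name_map, warnings


def paragroup_names(tree: HaplogroupTree) -> dict[str, str]:
    """sample id -> starred paragroup name for chromosomes at internal nodes."""
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node.children and node.samples:
            label = node.name or mutation_based_name(tree, node) or "?"
            for s in node.samples:
                out[s] = label + "*"
    return out


# ---------------------------------------------------------------------------
# refinement report


@dataclass
class RefinementReport:
    new_haplogroups: list[str] = field(default_factory=list)
    new_paragroups: list[str] = field(default_factory=list)
    resolved_polytomies: list[str] = field(default_factory=list)
    repositioned_markers: list[str] = field(default_factory=list)
    equivalence_classes: list[list[str]] = field(default_factory=list)
    per_clade: dict[str, int] = field(default_factory=dict)

    @property
    def n_new_haplogroups(self) -> int:
        return len(self.new_haplogroups)

    @property
    def n_new_paragroups(self) -> int:
        return len(self.new_paragroups)

    @property
    def n_resolved_polytomies(self) -> int:
        return len(self.resolved_polytomies)

    def to_dict(self) -> dict:
        return {
            "new_haplogroups": self.new_haplogroups,
            "n_new_haplogroups": self.n_new_haplogroups,
            "new_paragroups": self.new_paragroups,
            "n_new_paragroups": self.n_new_paragroups,
            "resolved_polytomies": self.resolved_polytomies,
            "n_resolved_polytomies": self.n_resolved_polytomies,
            "repositioned_markers": self.repositioned_markers,
            "equivalence_classes": self.equivalence_classes,
            "per_clade": self.per_clade,
        }

    def to_text(self) -> str:
        out = io.StringIO()
        out.write(f"new haplogroups ({self.n_new_haplogroups}): ")
        out.write(", ".join(self.new_haplogroups) or "none")
        out.write(f"\nnew paragroups ({self.n_new_paragroups}): ")
        out.write(", ".join(self.new_paragroups) or "none")
        out.write(
            f"\nresolved polytomies ({self.n_resolved_polytomies}): "
        )
        out.write(", ".join(self.resolved_polytomies) or "none")
        out.write("\nrepositioned markers: ")
        out.write(", ".join(self.repositioned_markers) or "none")
        out.write("\nmerged equivalence classes: ")
        out.write(
            "; ".join("{" + ", ".join(c) + "}" for c in self.equivalence_classes)
            or "none"
        )
        out.write("\nper-clade new haplogroups: ")
        out.write(
            ", ".join(f"{k}={v}" for k, v in sorted(self.per_clade.items())) or "none"
        )
        out.write("\n")
        return out.getvalue()


def _region_context_ok(
    tree: HaplogroupTree,
    node: HaplogroupNode,
    pm: dict,
    matched_named: dict[int, bool],
    prefixes: Optional[Sequence[str]],
) -> bool:
    if not prefixes:
        return True
    tokens = tree.signature(node) & _token_universe(tree)
    if tokens and all(any(t.startswith(p) for p in prefixes) for t in tokens):
        return True
    cur = pm.get(id(node))
    while cur is not None:
        if cur.name and matched_named.get(id(cur)):
            return any(cur.name.startswith(p) for p in prefixes)
        cur = pm.get(id(cur))
    return False


def _token_universe(tree: HaplogroupTree) -> frozenset[str]:
    return frozenset(n.token for n in tree.preorder() if n.token)


def diff_trees(
    backbone: HaplogroupTree,
    refined: HaplogroupTree,
    region_filter: Optional[Sequence[str]] = None,
) -> RefinementReport:
    """Compare a refined tree against the backbone it extends.

    Both trees must carry the same panel attachments (clades are compared
    by terminal content: leaf tokens plus sample ids).  ``region_filter``
    is a list of haplogroup-name prefixes (``["A", "B"]`` selects the
    African clades); it restricts the haplogroup/paragroup lists but not
    the marker-level lists.  Raises ``TreeError`` if ``refined`` does not
    contain every backbone clade (the inputs are then not a refinement
    pair).
    """
    back_sigs = {backbone.signature(n): n for n in backbone.preorder()}
    ref_sigs = {refined.signature(n): n for n in refined.preorder()}
    for sig, bnode in back_sigs.items():
        if (bnode.markers or bnode.name) and sig and sig not in ref_sigs:
            raise TreeError(
                f"backbone clade {bnode.name or sorted(sig)} missing from the"
                " refined tree: not a refinement pair"
            )

    pm = refined.parent_map()
    matched_named = {
        id(n): (refined.signature(n) in back_sigs) for n in refined.preorder()
    }

    report = RefinementReport()

    # new marker-defined clades
    for node in refined.preorder():
        if node is refined.root or not node.markers:
            continue
        sig = refined.signature(node)
        if sig in back_sigs:
            continue
        if node.origin == "repositioning":
            continue  # counted under resolved polytomies / repositions
        if node.collapsed:
            continue
        if not _region_context_ok(refined, node, pm, matched_named, region_filter):
            continue
        label = node.name or mutation_based_name(refined, node) or "?"
        report.new_haplogroups.append(label)
        letter = _clade_letter(refined, node)
        report.per_clade[letter] = report.per_clade.get(letter, 0) + 1

    # new paragroup residues
    back_host: dict[str, HaplogroupNode] = {}
    for n in backbone.preorder():
        for s in n.samples:
            back_host[s] = n
    for node in refined.preorder():
        if not node.children or not node.samples:
            continue
        if not _region_context_ok(refined, node, pm, matched_named, region_filter):
            continue
        sig = refined.signature(node)
        for s in sorted(node.samples):
            old = back_host.get(s)
            was_starred = old is not None and bool(old.children)
            same_host = old is not None and backbone.signature(old) == sig
            if was_starred and same_host:
                continue
            label = node.name or mutation_based_name(refined, node) or "?"
            report.new_paragroups.append(f"{label}*({s})")

    # resolved polytomies: matched clades whose out-degree went down
    for sig, bnode in back_sigs.items():
        rnode = ref_sigs.get(sig)
        if rnode is None:
            continue
        if len(rnode.children) < len(bnode.children):
            report.resolved_polytomies.append(
                f"{bnode.name or '?'}:{len(bnode.children)}->{len(rnode.children)}"
            )

    # repositioned markers: same marker, different clade
    back_branch: dict[str, frozenset[str]] = {}
    for n in backbone.preorder():
        for m in n.markers:
            back_branch[m] = backbone.signature(n)
    for n in refined.preorder():
        for m in n.markers:
            if m in back_branch and refined.signature(n) != back_branch[m]:
                report.repositioned_markers.append(m)
    report.repositioned_markers.sort()

    # equivalence classes merging backbone and newly placed markers
    backbone_markers = set(back_branch)
    for n in refined.preorder():
        if len(n.markers) > 1:
            have_old = any(m in backbone_markers for m in n.markers)
            have_new = any(m not in backbone_markers for m in n.markers)
            if have_old and have_new:
                report.equivalence_classes.append(sorted(n.markers))
    report.equivalence_classes.sort()
    report.new_haplogroups.sort()
    report.new_paragroups.sort()
    report.resolved_polytomies.sort()
    return report
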