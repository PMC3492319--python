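"""Character compatibility, perfect-phylogeny construction and placement.

Every marker is treated as a directed binary character: the ancestral
state is known (anchored by the outgroup at the root), so two markers are
compatible exactly when their derived-sample sets are nested or disjoint
on the chromosomes observed for both.  This is the directed analogue of
the four-gamete test, and a collection of markers admits a perfect
phylogeny (each marker mutating once) iff all pairs are compatible.

Placement maps markers one at a time onto an accepted backbone tree.  The
derived set of a marker, restricted to observed calls, pins it to

* an existing branch (declaring phylogenetic equivalence with the markers
  already there),
* a new node splitting a branch or grouping several sibling clades
  (``root_of_clade``; how a marker can join two previously separate
  haplogroups), or
* a new terminal branch below a node,

and when no-calls leave several branches consistent, the full candidate
set is retained, the most rootward candidate is used for reporting, and
the placement is flagged putative.  Nothing is imputed.  A marker whose
derived set cannot sit on any single branch is reported
``unplaced_incompatible`` — the signature of a recurrent mutation, which
callers may route to outgroup polarization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genotypes import (
    ANCESTRAL,
    DERIVED,
    NO_CALL,
    DerivedSet,
    GenotypeMatrix,
)
from .tree import HaplogroupNode, HaplogroupTree, TreeError

__all__ = [
    "PhylogenyError",
    "IncompatibleMarkersError",
    "Placement",
    "are_compatible",
    "build_perfect_phylogeny",
    "assign_samples",
    "audit_backbone_markers",
    "place_markers_on_backbone",
    "resolve_polytomy",
    "flag_putative",
    "equivalence_classes",
    "write_placement_report",
    "EXISTING_BRANCH",
    "SPLIT_BRANCH",
    "NEW_LEAF_BRANCH",
    "ROOT_OF_CLADE",
    "UNPLACED_INCOMPATIBLE",
    "AMBIGUOUS",
    "UNINFORMATIVE",
]

EXISTING_BRANCH = "existing_branch"
SPLIT_BRANCH = "split_branch"
NEW_LEAF_BRANCH = "new_leaf_branch"
ROOT_OF_CLADE = "root_of_clade"
UNPLACED_INCOMPATIBLE = "unplaced_incompatible"
AMBIGUOUS = "ambiguous"
# package extension: a marker with no observed derived call carries no
# placement information at all and is reported as such rather than forced
# onto a branch
UNINFORMATIVE = "unplaced_uninformative"


class PhylogenyError(ValueError):
    pass


class IncompatibleMarkersError(PhylogenyError):
    def __init__(self, marker_a: str, marker_b: str) -> None:
        self.pair = (marker_a, marker_b)
        super().__init__(
            f"markers {marker_a!r} and {marker_b!r} are incompatible:"
            " derived sets overlap without nesting"
        )


# ---------------------------------------------------------------------------
# compatibility


def are_compatible(a: DerivedSet, b: DerivedSet) -> bool:
    """Nested-or-disjoint test on the jointly observed chromosomes."""
    joint = a.observed & b.observed
    sa = a.members & joint
    sb = b.members & joint
    return sa <= sb or sb <= sa or not (sa & sb)


# ---------------------------------------------------------------------------
# perfect phylogeny from a complete matrix


def build_perfect_phylogeny(matrix: GenotypeMatrix) -> HaplogroupTree:
    """Unique minimal rooted tree realizing every derived set as a clade.

    Requires a complete matrix (no no-calls); incomplete data belongs to
    :func:`place_markers_on_backbone`.  Markers with identical derived
    sets are co-located on one branch.  Markers with an empty derived set
    carry no grouping information and are left off the tree.

    Raises :class:`IncompatibleMarkersError` naming an offending pair when
    no perfect phylogeny exists.
    """
    universe = frozenset(matrix.sample_ids)
    sets: dict[frozenset[str], list[str]] = {}
    for m in matrix.markers:
        ds = matrix.derived_set(m)
        if ds.observed != universe:
            raise PhylogenyError(
                f"marker {m!r} has no-calls; build_perfect_phylogeny needs"
                " a complete matrix"
            )
        if ds.members:
            sets.setdefault(ds.members, []).append(m)

    distinct = sorted(sets, key=lambda s: (-len(s), sorted(s)))
    # laminarity check doubles as the compatibility theorem: report the
    # first offending pair in deterministic (sorted-name) order
    for i, s in enumerate(distinct):
        for t in distinct[i + 1 :]:
            if s & t and not (s <= t or t <= s):
                a = min(sets[s])
                b = min(sets[t])
                raise IncompatibleMarkersError(*sorted((a, b)))

    root = HaplogroupNode(origin="placement")
    node_of: dict[frozenset[str], HaplogroupNode] = {}
    for s in distinct:  # parents precede children (size-descending)
        node = HaplogroupNode(markers=sorted(sets[s]), origin="placement")
        parent = root
        for t in distinct:
            if t is not s and s < t:
                # smallest strict superset seen so far wins; distinct is
                # size-descending so the last hit is the smallest
                parent = node_of[t]
        node_of[s] = node
        parent.children.append(node)

    # each sample becomes a leaf: on its singleton set's node when one
    # exists, else as a bare terminal child of the smallest containing set
    for sample in matrix.sample_ids:
        singleton = frozenset([sample])
        if singleton in node_of:
            node_of[singleton].samples.append(sample)
            continue
        best: Optional[frozenset[str]] = None
        for s in distinct:
            if sample in s and (best is None or len(s) < len(best)):
                best = s
        host = node_of[best] if best is not None else root
        host.children.append(HaplogroupNode(samples=[sample], origin="placement"))

    tree = HaplogroupTree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# sample assignment


def assign_samples(tree: HaplogroupTree, matrix: GenotypeMatrix) -> dict[str, HaplogroupNode]:
    """Attach each panel chromosome at its terminal backbone position.

    A sample descends into a child branch only when every *observed*
    marker of that branch is derived and at least one is (a wholly untyped
    branch is never entered — no imputation).  When recurrent data make
    two sibling branches qualify at once, descent stops conservatively at
    their parent.  Existing sample attachments on the tree are replaced.
    Off-path derived calls are ignored here; they surface later as marker
    inconsistencies during the backbone audit.
    """
    tree_markers = set(tree.all_markers())
    typed = [m for m in matrix.markers if m in tree_markers]
    for node in tree.preorder():
        node.samples = []
    positions: dict[str, HaplogroupNode] = {}
    for sid in matrix.sample_ids:
        cur = tree.root
        while True:
            nxt = None
            conflict = False
            for c in cur.children:
                calls = [matrix.state(sid, m) for m in c.markers if m in set(typed)]
                if calls and all(s != ANCESTRAL for s in calls) and DERIVED in calls:
                    if nxt is not None:
                        conflict = True  # recurrence: stay at the parent
                        break
                    nxt = c
            if nxt is None or conflict:
                break
            cur = nxt
        cur.samples.append(sid)
        positions[sid] = cur
    return positions


# ---------------------------------------------------------------------------
# backbone audit


def audit_backbone_markers(tree: HaplogroupTree, matrix: GenotypeMatrix) -> list[str]:
    """Backbone markers whose observed derived set contradicts their branch.

    A marker on branch *b* is contradicted when an observed-ancestral
    sample sits inside *b*'s clade, or a derived sample rests provably
    outside it — at a node that is neither in the subtree nor an ancestor
    of *b*.  A derived member resting at an ancestor is *not* a
    contradiction: its backbone calls were simply too incomplete to push
    it down, and no imputation is done.  Contradicted markers are
    candidates for repositioning (how a basal polytomy gets resolved when
    new genotyping shows a marker's derived allele extends beyond its
    published branch).
    """
    bad: list[str] = []
    in_matrix = set(matrix.markers)
    positions = tree.sample_positions()
    pm = tree.parent_map()
    for node in tree.preorder():
        if node is tree.root:
            continue
        clade = tree.clade_samples(node)
        ancestors: set[int] = set()
        cur = pm[id(node)]
        while cur is not None:
            ancestors.add(id(cur))
            cur = pm[id(cur)]
        for m in node.markers:
            if m not in in_matrix:
                continue
            ds = matrix.derived_set(m)
            outside = any(
                s not in clade and id(positions[s]) not in ancestors
                for s in ds.members
                if s in positions
            )
            if outside or (ds.observed - ds.members) & clade:
                bad.append(m)
    return sorted(bad)


# ---------------------------------------------------------------------------
# placement


@dataclass
class Placement:
    """Where one marker landed, and how sure the data allow us to be."""

    marker: str
    mode: str
    node: Optional[HaplogroupNode] = None
    candidates: list[HaplogroupNode] = field(default_factory=list)
    equivalence_class: list[str] = field(default_factory=list)
    putative: bool = False
    original_branch: Optional[str] = None
    note: str = ""


def _descend(tree: HaplogroupTree, members: frozenset[str]) -> HaplogroupNode:
    """Deepest node whose clade still contains every derived sample."""
    cur = tree.root
    while True:
        if set(cur.samples) & members:
            return cur
        nxt = None
        for c in cur.children:
            if members <= tree.clade_samples(c):
                nxt = c
                break
        if nxt is None:
            return cur
        cur = nxt


def _place_one(
    tree: HaplogroupTree,
    ds: DerivedSet,
    origin: str,
) -> Placement:
    members, observed = ds.members, ds.observed
    if not members:
        return Placement(
            ds.marker,
            UNINFORMATIVE,
            putative=True,
            note="no derived call observed",
        )

    stop = _descend(tree, members)
    pm = tree.parent_map()

    # existing-branch candidates: the consistent chain from the stop node
    # rootward (consistency can only be lost, never regained, going up)
    chain: list[HaplogroupNode] = []
    node: Optional[HaplogroupNode] = stop
    while node is not None and node is not tree.root:
        clade = tree.clade_samples(node)
        if members <= clade and not (observed - members) & clade:
            chain.append(node)
            node = pm[id(node)]
        else:
            break

    # minimal new-node grouping at the stop node.  Children with no
    # observed call at this marker cannot be grouped in (no imputation),
    # but their relation to the new branch is then untestable: the
    # placement is flagged putative below.
    new_candidate: Optional[tuple[str, list[HaplogroupNode], list[str]]] = None
    inside: list[HaplogroupNode] = []
    coverable = True
    untestable_children = 0
    spanned: set[str] = set()
    for c in stop.children:
        cs = tree.clade_samples(c)
        if not cs & observed:
            untestable_children += 1
        if cs & members:
            inside.append(c)
            spanned.update(cs & members)
            if (observed - members) & cs:
                coverable = False  # child partly ancestral: cannot be grouped
    member_samples = sorted(set(stop.samples) & members)
    spanned.update(member_samples)
    if spanned != set(members):
        # members escape the stop node's immediate content: impossible
        coverable = False
    whole_content = len(inside) == len(stop.children) and set(member_samples) == set(
        stop.samples
    )
    if coverable and not whole_content and (inside or member_samples):
        if not inside:
            mode = NEW_LEAF_BRANCH
        elif len(inside) == 1 and not member_samples:
            mode = None  # grouping one full child alone is just that branch
        elif len(inside) == 1:
            mode = SPLIT_BRANCH
        else:
            mode = ROOT_OF_CLADE
        if mode is not None:
            new_candidate = (mode, inside, member_samples)

    n_candidates = len(chain) + (1 if new_candidate else 0)
    if n_candidates == 0:
        return Placement(
            ds.marker,
            UNPLACED_INCOMPATIBLE,
            note="derived set fits no single branch (candidate recurrent mutation)",
        )

    def _add_marker(nd: HaplogroupNode) -> None:
        nd.markers = sorted(set(nd.markers) | {ds.marker})

    if n_candidates == 1 and new_candidate is not None:
        mode, inside, member_samples = new_candidate
        new_node = HaplogroupNode(
            markers=[ds.marker],
            children=list(inside),
            samples=list(member_samples),
            origin=origin,
        )
        kept: list[HaplogroupNode] = []
        placed = False
        for c in stop.children:
            if c in inside:
                if not placed:
                    kept.append(new_node)
                    placed = True
            else:
                kept.append(c)
        if not placed:
            kept.append(new_node)
        stop.children = kept
        stop.samples = [s for s in stop.samples if s not in set(member_samples)]
        putative = untestable_children > 0
        return Placement(
            ds.marker,
            mode,
            node=new_node,
            candidates=[new_node],
            putative=putative,
            note=(
                f"{untestable_children} sibling lineage(s) untyped at this"
                " marker; their relation to the new branch is untestable"
                if putative
                else ""
            ),
        )

    # one or more existing candidates (plus possibly a new-node reading):
    # report on the most rootward existing branch; >1 readings = ambiguous
    target = chain[-1] if chain else None
    if target is None:  # pragma: no cover - chain empty implies new_candidate only
        raise PhylogenyError("internal: no target with candidates present")
    _add_marker(target)
    candidates = list(reversed(chain))  # rootward first
    if new_candidate is not None:
        # the finer reading (a new branch below) stays hypothetical; it is
        # recorded in the note rather than materialized on the tree
        return Placement(
            ds.marker,
            AMBIGUOUS,
            node=target,
            candidates=candidates,
            putative=True,
            note="existing branch vs finer new branch, untestable with"
            " observed calls",
        )
    if len(candidates) > 1:
        return Placement(
            ds.marker,
            AMBIGUOUS,
            node=target,
            candidates=candidates,
            putative=True,
            note="several rootward branches consistent under no-calls",
        )
    return Placement(ds.marker, EXISTING_BRANCH, node=target, candidates=candidates)


def place_markers_on_backbone(
    backbone: HaplogroupTree,
    matrix: GenotypeMatrix,
    markers: Optional[Sequence[str]] = None,
) -> tuple[list[Placement], HaplogroupTree]:
    """Map markers onto a backbone; returns placements and the refined tree.

    The backbone is first audited: samples are attached from their
    backbone-marker calls, and any backbone marker contradicted by the
    data is pulled off its branch and re-placed alongside the new markers
    (rootward-first, ties by name, for deterministic output).  The input
    tree is not modified.
    """
    refined = backbone.copy()
    refined.validate()
    assign_samples(refined, matrix)

    repositioned = audit_backbone_markers(refined, matrix)
    for m in repositioned:
        br = refined.find_marker_branch(m)
        br.markers = [x for x in br.markers if x != m]
    original_branch = {}
    for m in repositioned:
        original_branch[m] = backbone.find_marker_branch(m).name

    on_tree = set(refined.all_markers())
    if markers is None:
        markers = [m for m in matrix.markers]
    queue: list[str] = []
    placements: list[Placement] = []
    for m in markers:
        if m in on_tree:
            node = refined.find_marker_branch(m)
            placements.append(
                Placement(m, EXISTING_BRANCH, node=node, candidates=[node],
                          note="backbone marker, consistent")
            )
        else:
            queue.append(m)
    # repositioned markers must be re-placed even when outside the
    # caller's selection: no marker is ever lost
    queue.extend(m for m in repositioned if m not in set(queue))

    queue.sort(key=lambda m: (-len(matrix.derived_set(m).members), m))
    for m in queue:
        origin = "repositioning" if m in original_branch else "placement"
        pl = _place_one(refined, matrix.derived_set(m), origin)
        pl.original_branch = original_branch.get(m)
        placements.append(pl)

    classes = equivalence_classes(refined)
    for pl in placements:
        if pl.node is not None and pl.node.markers:
            pl.equivalence_class = classes.get(pl.node.markers[0], [pl.marker])
    placements.sort(key=lambda p: p.marker)
    refined.validate()
    return placements, refined


def equivalence_classes(tree: HaplogroupTree) -> dict[str, list[str]]:
    """Marker -> sorted co-branch marker list (size >= 1)."""
    out: dict[str, list[str]] = {}
    for node in tree.preorder():
        if node.markers:
            cls = sorted(node.markers)
            for m in cls:
                out[m] = cls
    return out


# ---------------------------------------------------------------------------
# polytomy resolution


def resolve_polytomy(
    tree: HaplogroupTree, marker: str, matrix: GenotypeMatrix
) -> HaplogroupTree:
    """Reposition ``marker`` to group the polytomy children it spans.

    The marker must currently sit on one child branch of a multifurcation;
    if its observed derived set covers two or more (but not all) sibling
    clades, it is moved to a new internal node grouping exactly those
    children, strictly reducing the polytomy's out-degree.  A derived set
    confined to the marker's own child is left untouched; one covering
    every child means the marker belongs above the polytomy and is the
    business of :func:`place_markers_on_backbone`, not this operation.
    """
    out = tree.copy()
    branch = out.find_marker_branch(marker)
    pm = out.parent_map()
    parent = pm[id(branch)]
    if parent is None:
        raise PhylogenyError(f"marker {marker!r} sits above the root")
    ds = matrix.derived_set(marker)
    covered = [
        c for c in parent.children if out.clade_samples(c) & ds.members
    ]
    for c in covered:
        if (ds.observed - ds.members) & out.clade_samples(c):
            raise PhylogenyError(
                f"marker {marker!r}: derived set straddles child"
                f" {c.name!r} (partly ancestral)"
            )
    extra = ds.members - out.clade_samples(parent)
    if extra:
        raise PhylogenyError(
            f"marker {marker!r}: derived samples {sorted(extra)} outside the"
            " polytomy; reposition via place_markers_on_backbone"
        )
    if len(covered) == len(parent.children):
        raise PhylogenyError(
            f"marker {marker!r} covers every child: it belongs above the"
            " polytomy node, not inside it"
        )
    if len(covered) <= 1:
        return out  # nothing to resolve
    branch.markers = [m for m in branch.markers if m != marker]
    new_node = HaplogroupNode(
        markers=[marker], children=list(covered), origin="repositioning"
    )
    kept: list[HaplogroupNode] = []
    placed = False
    for c in parent.children:
        if c in covered:
            if not placed:
                kept.append(new_node)
                placed = True
        else:
            kept.append(c)
    parent.children = kept
    out.validate()
    return out


# ---------------------------------------------------------------------------
# putative flagging


def flag_putative(
    tree: HaplogroupTree, matrix: GenotypeMatrix, in_place: bool = False
) -> HaplogroupTree:
    """Flag branches with no derived positive control (drawn dashed).

    A branch is supported when some sample carries an observed derived
    call at one of its markers, or when it is a bare terminal branch
    holding an observed chromosome.  Everything else — markers typed
    nowhere, splits inferred only from absence patterns — is putative.
    """
    out = tree if in_place else tree.copy()
    in_matrix = set(matrix.markers)
    for node in out.preorder():
        if node is out.root:
            node.putative = False
            continue
        supported = False
        for m in node.markers:
            if m in in_matrix and matrix.derived_set(m).members:
                supported = True
                break
        if not node.markers and (node.samples or not node.children):
            # bare sample holder: the chromosome itself is the control
            supported = bool(node.samples)
        node.putative = not supported
    return out


# ---------------------------------------------------------------------------
# reporting


def write_placement_report(
    placements: Iterable[Placement], stream: Optional[io.TextIOBase] = None
) -> str:
    """TSV: marker, mode, target, equivalence_class, putative, original, note."""
    out = io.StringIO()
    out.write("marker\tmode\ttarget\tcandidates\tequivalence_class\tputative"
              "\toriginal_branch\tnote\n")
    for p in placements:
        target = p.node.name if (p.node and p.node.name) else ""
        cands = "|".join(
            c.name for c in p.candidates if c.name
        )
        eq = "|".join(p.equivalence_class)
        out.write(
            "\t".join(
                [
                    p.marker,
                    p.mode,
                    target,
                    cands,
                    eq,
                    "1" if p.putative else "0",
                    p.original_branch or "",
                    p.note,
                ]
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
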