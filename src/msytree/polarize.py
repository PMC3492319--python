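"""Outgroup polarization of recurrent and triallelic sites.

A site showing three alleles across the panel plus the outgroup (or two
alleles whose derived set contradicts the tree) cannot be a unique-event
polymorphism.  With the root state anchored to the outgroup allele, the
minimum set of mutation events explaining every raw call is found by
exact small parsimony (Sankoff dynamic programming) over the haplogroup
tree, with panel chromosomes hanging off their resolved nodes as fixed
terminal observations.

Each event is assigned to the branch subtending exactly the chromosomes
that inherit its target allele (absent a later overwrite), and events at
one site are named ``<site>.1``, ``<site>.2``, ... in pre-order of their
branches — a reporting convention, not an inference about discovery
order.  Ties among equally parsimonious assignments are broken toward the
more rootward branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .genotypes import GenotypeMatrix
from .markers import OutgroupAllele, base_site
from .tree import HaplogroupNode, HaplogroupTree

__all__ = [
    "MutationEvent",
    "PolarizationError",
    "polarize_multiallelic",
    "detect_multiallelic_sites",
    "apply_polarization",
    "replay_events",
    "write_polarization_report",
]

_INF = 10**9


class PolarizationError(ValueError):
    pass


@dataclass(frozen=True)
class SampleEdge:
    """The terminal branch of one panel chromosome below its host node."""

    host: HaplogroupNode
    sample: str

    @property
    def label(self) -> str:
        return f"sample:{self.sample}"


@dataclass
class MutationEvent:
    base_site: str
    event_name: str
    from_allele: str
    to_allele: str
    branch: Union[HaplogroupNode, SampleEdge]
    alternatives: list[str] = field(default_factory=list)

    @property
    def branch_label(self) -> str:
        if isinstance(self.branch, SampleEdge):
            return self.branch.label
        if self.branch.name:
            return self.branch.name
        if self.branch.markers:
            return f"branch({self.branch.markers[0]})"
        return "unnamed"


def polarize_multiallelic(
    site: str,
    raw_calls: Mapping[str, str],
    outgroup: Union[str, OutgroupAllele],
    tree: HaplogroupTree,
) -> list[MutationEvent]:
    """Minimum mutation events explaining ``raw_calls`` on ``tree``.

    ``raw_calls`` maps sample id -> observed nucleotide (samples without a
    call are simply unconstrained).  The root state is fixed to the
    outgroup allele; a missing outgroup is an error because the events
    cannot be rooted.
    """
    if outgroup is None:
        raise PolarizationError(
            f"site {site!r}: no outgroup call, events cannot be rooted"
        )
    root_allele = outgroup.allele if isinstance(outgroup, OutgroupAllele) else outgroup
    calls = {s: a.upper() for s, a in raw_calls.items() if a}
    positions = tree.sample_positions()
    missing = sorted(set(calls) - set(positions))
    if missing:
        raise PolarizationError(
            f"site {site!r}: samples {missing} carry calls but sit on no"
            " tree node"
        )
    alphabet = sorted(set(calls.values()) | {root_allele})

    # Sankoff upward pass; every called sample is a fixed pseudo-leaf
    cost: dict[int, dict[str, int]] = {}

    def up(node: HaplogroupNode) -> None:
        for c in node.children:
            up(c)
        table = {}
        for a in alphabet:
            total = 0
            for c in node.children:
                total += min(cost[id(c)][b] + (a != b) for b in alphabet)
            for s in node.samples:
                if s in calls:
                    total += int(calls[s] != a)
            table[a] = total
        cost[id(node)] = table

    up(tree.root)

    # downward pass: root fixed; ties resolved toward taking the new
    # allele as early (rootward) as possible, then lexicographically
    state: dict[int, str] = {id(tree.root): root_allele}
    order: list[tuple[HaplogroupNode, Optional[HaplogroupNode]]] = []

    def down(node: HaplogroupNode) -> None:
        a = state[id(node)]
        for c in node.children:
            scores = {b: cost[id(c)][b] + (a != b) for b in alphabet}
            best = min(scores.values())
            ties = sorted(b for b, v in scores.items() if v == best)
            non_parent = [b for b in ties if b != a]
            state[id(c)] = non_parent[0] if non_parent else a
            order.append((c, node))
            down(c)

    down(tree.root)

    events: list[MutationEvent] = []

    def visit(node: HaplogroupNode, parent: Optional[HaplogroupNode]) -> None:
        if parent is not None and state[id(node)] != state[id(parent)]:
            events.append(
                MutationEvent(
                    base_site=base_site(site),
                    event_name="",
                    from_allele=state[id(parent)],
                    to_allele=state[id(node)],
                    branch=node,
                )
            )
        for s in node.samples:
            if s in calls and calls[s] != state[id(node)]:
                events.append(
                    MutationEvent(
                        base_site=base_site(site),
                        event_name="",
                        from_allele=state[id(node)],
                        to_allele=calls[s],
                        branch=SampleEdge(node, s),
                    )
                )
        for c in node.children:
            visit(c, node)

    visit(tree.root, None)

    base = base_site(site)
    if len(events) == 1:
        events[0].event_name = base
    else:
        for k, ev in enumerate(events, start=1):
            ev.event_name = f"{base}.{k}"
    return events


def detect_multiallelic_sites(
    matrix: GenotypeMatrix,
    outgroup: Mapping[str, OutgroupAllele],
) -> list[str]:
    """Markers showing >=3 distinct alleles across panel plus outgroup."""
    if not matrix.has_raw_alleles:
        return []
    out = []
    for m in matrix.markers:
        alleles = {
            matrix.raw_allele(s, m) for s in matrix.sample_ids if matrix.raw_allele(s, m)
        }
        og = outgroup.get(base_site(m))
        if og is not None:
            alleles.add(og.allele)
        if len(alleles) >= 3:
            out.append(m)
    return out


def apply_polarization(
    tree: HaplogroupTree, site: str, events: list[MutationEvent]
) -> None:
    """Rewrite ``site`` on ``tree`` as its constituent events, in place.

    The original marker name is removed wherever it sits; each event's
    name is added to its branch.  An event private to a single chromosome
    founds a new terminal branch below its host node.  Events must
    reference nodes of ``tree`` (i.e. come from polarizing this tree).
    """
    for node in tree.preorder():
        if site in node.markers:
            node.markers = [m for m in node.markers if m != site]
    for ev in events:
        if isinstance(ev.branch, SampleEdge):
            host, sample = ev.branch.host, ev.branch.sample
            if sample not in host.samples:
                raise PolarizationError(
                    f"event {ev.event_name}: sample {sample!r} not at its host node"
                )
            if not host.children and host.samples == [sample]:
                host.markers = sorted(set(host.markers) | {ev.event_name})
                continue
            host.samples = [s for s in host.samples if s != sample]
            host.children.append(
                HaplogroupNode(
                    markers=[ev.event_name], samples=[sample], origin="placement"
                )
            )
        else:
            ev.branch.markers = sorted(set(ev.branch.markers) | {ev.event_name})


def replay_events(
    tree: HaplogroupTree,
    events: list[MutationEvent],
    root_allele: str,
) -> dict[str, str]:
    """Propagate events down the tree; returns sample -> resulting allele."""
    edge_change: dict[int, str] = {}
    sample_change: dict[tuple[int, str], str] = {}
    for ev in events:
        if isinstance(ev.branch, SampleEdge):
            sample_change[(id(ev.branch.host), ev.branch.sample)] = ev.to_allele
        else:
            edge_change[id(ev.branch)] = ev.to_allele

    out: dict[str, str] = {}

    def walk(node: HaplogroupNode, allele: str) -> None:
        allele = edge_change.get(id(node), allele)
        for s in node.samples:
            out[s] = sample_change.get((id(node), s), allele)
        for c in node.children:
            walk(c, allele)

    walk(tree.root, root_allele)
    return out


def write_polarization_report(
    events: list[MutationEvent], stream: Optional[io.TextIOBase] = None
) -> str:
    """TSV: base_site, event_name, from, to, branch, alternatives."""
    out = io.StringIO()
    out.write("base_site\tevent_name\tfrom\tto\tbranch\talternatives\n")
    for ev in events:
        out.write(
            "\t".join(
                [
                    ev.base_site,
                    ev.event_name,
                    ev.from_allele,
                    ev.to_allele,
                    ev.branch_label,
                    "|".join(ev.alternatives),
                ]
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
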