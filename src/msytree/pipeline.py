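"""End-to-end refinement: backbone + panel genotypes -> refined tree + report.

The stages, in order:

1. copy the backbone and attach each panel chromosome at the deepest
   position its backbone-marker calls support;
2. audit the backbone markers against the data; contradicted markers are
   pulled off their branches and re-placed with everything else (this is
   how a polytomy gets resolved by repositioning);
3. place all remaining typed markers, rootward-first;
4. decompose multiallelic sites (three alleles across panel + outgroup,
   or binary markers left unplaced as incompatible) into independent
   mutation events by outgroup polarization, rewriting ``site`` into
   ``site.1``, ``site.2``, ... on their branches;
5. flag putative branches (no derived positive control);
6. assign mutation-based and lineage-based names to new nodes;
7. diff the refined tree against the backbone.

Every stage is also available separately; this module only sequences
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .genotypes import GenotypeMatrix
from .markers import MarkerCatalog, OutgroupAllele, base_site
from .nomenclature import RefinementReport, assign_names, diff_trees, paragroup_names
from .phylogeny import (
    UNPLACED_INCOMPATIBLE,
    Placement,
    assign_samples,
    flag_putative,
    place_markers_on_backbone,
)
from .polarize import (
    MutationEvent,
    apply_polarization,
    detect_multiallelic_sites,
    polarize_multiallelic,
)
from .tree import HaplogroupTree

__all__ = ["RefinementResult", "refine"]


@dataclass
class RefinementResult:
    backbone: HaplogroupTree          # with panel attachments, for diffing
    refined: HaplogroupTree
    placements: list[Placement]
    events: list[MutationEvent] = field(default_factory=list)
    report: Optional[RefinementReport] = None
    naming_warnings: list[str] = field(default_factory=list)

    @property
    def paragroups(self) -> dict[str, str]:
        return paragroup_names(self.refined)


def refine(
    backbone: HaplogroupTree,
    matrix: GenotypeMatrix,
    catalog: Optional[MarkerCatalog] = None,
    outgroup: Optional[Mapping[str, OutgroupAllele]] = None,
    region_filter: Optional[Sequence[str]] = None,
) -> RefinementResult:
    """Run the whole mapping pipeline; inputs are not modified."""
    placements, refined = place_markers_on_backbone(backbone, matrix)

    events: list[MutationEvent] = []
    if outgroup is not None and matrix.has_raw_alleles:
        sites = set(detect_multiallelic_sites(matrix, outgroup))
        # binary markers that failed placement are recurrence candidates:
        # polarize them too when an outgroup call exists
        for pl in placements:
            if pl.mode == UNPLACED_INCOMPATIBLE and base_site(pl.marker) in outgroup:
                sites.add(pl.marker)
        for site in sorted(sites):
            raw_calls = {
                sid: matrix.raw_allele(sid, site) for sid in matrix.sample_ids
            }
            og = outgroup.get(base_site(site))
            if og is None:
                continue
            site_events = polarize_multiallelic(site, raw_calls, og, refined)
            if len(site_events) > 1:
                apply_polarization(refined, site, site_events)
            events.extend(site_events)

    # in place: placements hold references into this tree
    flag_putative(refined, matrix, in_place=True)
    refined, _, warnings = assign_names(refined)

    bb = backbone.copy()
    assign_samples(bb, matrix)
    report = diff_trees(bb, refined, region_filter)

    return RefinementResult(
        backbone=bb,
        refined=refined,
        placements=placements,
        events=events,
        report=report,
        naming_warnings=warnings,
    )
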