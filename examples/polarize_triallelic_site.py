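"""Decompose a triallelic site into two mutation events with an outgroup.

V161 was first reported as a biallelic G->C transversion on the deep A1b
branch.  The chimpanzee reference carries A at the orthologous position, a
third allele: with the root anchored to A, minimum parsimony on the
refined tree explains the calls as two independent mutations.
"""

from msytree import AFRICAN_CLADES, refine, reference_panel

panel = reference_panel()
result = refine(panel.backbone, panel.matrix, panel.catalog, panel.outgroup,
                region_filter=AFRICAN_CLADES)

for ev in result.events:
    print(f"{ev.event_name}: {ev.from_allele} -> {ev.to_allele} "
          f"on branch {ev.branch_label}")
# V161.1: A -> C inside the A1b lineage (all four panel chromosomes carry C)
# V161.2: A -> G at the root of everything else (the A1a-T stem)
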