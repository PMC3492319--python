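"""Parse the packaged marker table and query it by name range.

The table lists 22 newly described Y-chromosome mutations in the published
dialect (GRCh37 coordinates; multi-copy and deletion rows included).
"""

from msytree import new_mutation_table

catalog = new_mutation_table()
print(f"markers parsed: {len(catalog)}")

first = catalog.select_by_name_range(2, 249)
second = catalog.select_by_name_range(262, 317)
print(f"V2-V249 (from the discovery database): {len(first)}")
print(f"V262-V317 (from re-sequencing two A3b chromosomes): {len(second)}")

v249 = catalog["V249"]
print(f"V249 hits {len(v249.positions)} paralogous copies: {v249.positions}")
for name in ("V303", "V304"):
    m = catalog[name]
    print(f"{name}: deletion of {m.ancestral} ({m.span} bp at "
          f"{m.positions[0]}-{m.positions[1]})")

# The counts partition the table: 11 + 9 + 2 (V254, V341, found during
# mapping) = 22.
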