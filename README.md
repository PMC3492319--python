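# msytree

Phylogenetic mapping of Y-chromosome binary markers onto haplogroup trees.

The male-specific region of the Y chromosome (MSY) does not recombine, so
its variation forms a single genealogy and every biallelic marker — a
unique-event polymorphism (UEP) — belongs to exactly one branch of it.
Given a published backbone tree, a catalog of markers, and a panel of
representative chromosomes typed at those markers, `msytree`:

* places each marker on the branch its derived-sample set pins down
  (declaring **phylogenetic equivalence** when it matches an existing
  branch, founding a **new haplogroup** when it refines one, or grouping
  sibling clades into a new node when it spans them);
* **repositions** backbone markers the new genotypes contradict, which is
  how an unresolved polytomy gets resolved;
* decomposes **triallelic/recurrent sites** into independent mutation
  events by minimum parsimony, rooted on an outgroup (chimpanzee) allele;
* flags branches with no derived positive control as **putative** (the
  dashed branches of tree figures);
* names new nodes in both field conventions — frozen mutation-based names
  (`A-V218`) and extendable lineage labels (`C7`) — with paragroups
  rendered with a trailing `*`;
* reports the refinement as a structured diff against the backbone.

The core formal tool is the directed perfect phylogeny: markers with known
ancestral state are pairwise compatible iff their derived sets are nested
or disjoint, and a collection of markers fits a tree in which each mutates
once iff all pairs are compatible. `msytree` implements the construction,
the placement logic for incomplete data (no imputation; most-rootward
consistent branch, candidate sets retained, putative flags), and a panel
simulator with known truth for end-to-end validation.

## Worked example

The package ships a reference panel encoding a survey of the deepest
(African) portion of the MSY tree: a redrawn backbone, a catalog
including 22 newly described mutations with printed GRCh37 coordinates,
and a genotype matrix for 51 representative chromosomes typed in
per-haplogroup panels.

```python
from msytree import AFRICAN_CLADES, refine, reference_panel

panel = reference_panel()

# 19 of the 32 candidate markers are shared by all four deep-lineage
# (A1b panel) chromosomes:
spec = panel.panels["A1b"]
print(panel.matrix.shared_derived_count(spec.samples, spec.markers))  # 19

result = refine(panel.backbone, panel.matrix, panel.catalog,
                panel.outgroup, region_filter=AFRICAN_CLADES)
print(result.report.n_new_haplogroups)        # 15
print(result.report.resolved_polytomies)      # ['B2:3->2']
print(result.report.repositioned_markers)     # ['M112', 'P289']
```

The run reports 15 new African haplogroups (10 in clade A, 5 in clade B),
resolves the B2a/B2b/B2c trifurcation by repositioning M112 to a new node
grouping B2b with B2c, moves P289 upstream of both A3 sub-clades, and
finds the published equivalences V73 ≡ M114 and V249 ≡ PK1. The
triallelic V161 site (outgroup allele A; panel alleles C and G) resolves
into two events, `V161.1: A→C` inside the A1b lineage and `V161.2: A→G`
at the root of its sister clade. Short narrative scripts for each
capability live in `examples/`.

## Command line

```sh
msytree fixture  --out fixture/                 # materialize the panel files
msytree refine   --backbone fixture/backbone.nwk --catalog fixture/catalog.tsv \
                 --matrix fixture/matrix.tsv --raw-alleles fixture/raw_alleles.tsv \
                 --outgroup fixture/outgroup.tsv --region-filter A,B --out out/
msytree simulate --n-leaves 8 --seed 42 --out sim/
```

`refine` writes the refined annotated Newick, a placement table, a
polarization table, and a machine-readable summary.

## Layout

| path | contents |
| --- | --- |
| `src/msytree/markers.py` | marker catalog, published + canonical TSV dialects |
| `src/msytree/genotypes.py` | D/A/N genotype matrix, derived sets |
| `src/msytree/tree.py` | annotated haplogroup trees, Newick I/O |
| `src/msytree/phylogeny.py` | compatibility, perfect phylogeny, placement |
| `src/msytree/polarize.py` | outgroup polarization of multiallelic sites |
| `src/msytree/nomenclature.py` | naming, paragroups, refinement diff |
| `src/msytree/simulate.py` | panel simulator with known truth |
| `src/msytree/refpanel.py` | the packaged reference panel |
| `src/msytree/pipeline.py` | end-to-end `refine()` |
| `docs/methods.md` | model, conventions, guarantees, limitations |
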