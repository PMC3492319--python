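# Methods

## Model

The MSY genealogy is a rooted tree whose branches carry unique-event
polymorphisms (UEPs): each marker mutated exactly once, so the chromosomes
carrying its derived allele are exactly the clade below its branch. With
the ancestral state known (anchored by the outgroup at the root), two
markers are compatible iff their derived-sample sets are nested or
disjoint — the directed form of the four-gamete test, evaluated only on
chromosomes observed for both markers. A set of markers admits a perfect
phylogeny iff all pairs are compatible; the minimal realizing tree is then
unique and its non-trivial clades are exactly the distinct derived sets.

`build_perfect_phylogeny` implements the laminar-family construction for
complete matrices: distinct derived sets are sorted by size, checked for
laminarity (the first offending pair is reported by name — the signature
of a recurrent mutation), and turned into a containment tree; markers with
identical derived sets share a branch (phylogenetic equivalence); each
chromosome becomes a terminal, on its private branch when one exists.

## Placement on a backbone

Real studies do not rebuild the tree from scratch; they map markers onto
an accepted backbone. `place_markers_on_backbone`:

1. attaches each chromosome at the deepest backbone position its observed
   backbone-marker calls support (never entering a branch with no derived
   call — no imputation; a recurrence-induced conflict stops descent at
   the parent);
2. audits backbone markers: one is contradicted when an observed-ancestral
   chromosome sits inside its clade or a derived carrier rests provably
   outside (resting at an *ancestor* is not evidence of contradiction,
   only of unresolved position). Contradicted markers are pulled off and
   re-placed with everything else — this is how the B2 trifurcation
   resolves when M112 turns out to be derived in B2c as well;
3. places markers rootward-first (larger derived sets first, ties by
   name, so output is deterministic and parents are created before
   children). For each marker the engine finds the chain of existing
   branches consistent with the observed calls plus, at the bottom, the
   minimal new-node grouping (split of one edge, grouping of several
   sibling clades, or a new terminal branch). One candidate → that
   placement; several → mode `ambiguous`, the most rootward existing
   branch used for reporting, the placement flagged putative. A marker
   whose derived set fits no single branch is `unplaced_incompatible`; one
   with no derived call at all is reported `unplaced_uninformative` (a
   package extension to the mode list — such a marker carries no
   placement information and is not forced anywhere).

### Missing data: the exact guarantee

Without no-calls and with every true branch marker-bearing and every
lineage sampled, placement recovers the true tree exactly (tested on 100
seeded simulations). With no-calls the guarantees are deliberately
weaker, because wholly-untyped sibling lineages make some groupings
untestable and no deterministic choice can always match the truth. What
the engine guarantees, and the suite asserts:

* every placed marker explains all its observed calls (no
  observed-ancestral chromosome inside its clade);
* derived carriers never rest provably outside their marker's clade at
  placement time (they may rest above it, unresolved);
* any new node whose grouping excludes a wholly-untyped sibling lineage is
  flagged putative on its placement, and any refined clade that crosses a
  true clade (restricted to chromosomes resolved to their true terminal
  positions) is one of those flagged nodes.

The minimal grouping (excluding untyped lineages) is materialized rather
than the maximal one: including an untyped lineage would impute a derived
state nobody observed.

## Outgroup polarization

A site with three alleles across panel + outgroup, or a binary marker left
unplaced as incompatible, is decomposed by exact small parsimony (Sankoff
dynamic programming) over the refined tree, with the root state fixed to
the outgroup allele and each called chromosome hanging off its resolved
node as a fixed pseudo-leaf. Ties are broken toward taking a new allele as
early (rootward) as possible, then lexicographically — so a private
derived allele lands on the subtending branch, not the terminal edge.
Events are named `<site>.1`, `<site>.2`, … in pre-order of their branches;
this numbering is a reporting convention (pre-order matches the drawing
order of tree figures), not an inference about mutation order. A single
event keeps the site's original name. Event chains (an event reading from
another's target allele) arise exactly when their branches are
ancestor–descendant, otherwise all events read from the outgroup allele.
The suite checks minimality against brute-force enumeration on small trees
and that replaying events down the tree reproduces every raw call.

## Nomenclature and the refinement report

Mutation-based names (`A-V218`) are frozen: major-clade letter +
lexicographically-first marker of the branch. Lineage labels extend the
parent's label with the next free digit/letter (alternating), and are
assigned only to new *terminal* branches — a node inserted above existing
structure keeps its mutation-based name only, so published labels are
never re-lettered. Paragroup residues (chromosomes derived at a node but
ancestral/untyped at all its children) render as `name*`. A putative
branch with no marker gets an explicit placeholder plus a warning.

`diff_trees` compares clades by *terminal signature* (backbone leaf tokens
plus chromosome ids; tokens persist when a leaf gains children, so
backbone and refined clades stay comparable). Counting conventions:

* **new haplogroup** — a marker-defined clade of the refined tree whose
  signature matches no backbone clade, excluding nodes created by
  repositioning a marker the backbone already carried (those are reported
  under resolved polytomies / repositioned markers) and collapsed
  subtrees;
* **new paragroup** — a chromosome newly left resting at an internal node
  where the backbone did not already star it;
* **resolved polytomy** — a matched clade whose out-degree strictly
  decreased;
* the region filter is a clade-name prefix allow-list (`["A", "B"]`
  selects the African clades); a node qualifies through its leaf tokens
  or, for sample-only clades, its nearest backbone-matched named ancestor.

Under these conventions the packaged panel yields 15 new African
haplogroups (A1b 3, A1a 1, A2 1, A3 5, B2a 5): the refined terminal
defined by P114 plus three equivalent markers matches the backbone clade
and is therefore not counted as new, and the A2+A3 grouping is part of
the backbone (PK1), so V249 contributes an equivalence rather than a node.

## The panel simulator

`simulate_tree_and_markers` draws a random rooted binary genealogy
(coalescent-style joins), paints each branch with
Poisson(`mean_markers_per_branch`) substitution markers (default 3.0 —
a typical per-branch marker density for re-sequencing-era basal-tree
surveys; `min_markers_per_branch` can force every branch detectable, which
the recovery guarantees require), and emits the outgroup table (root
alleles). `genotype_panel` types one-to-few representatives per lineage —
representative sampling, not population-frequency sampling, because the
analysis is placement, not frequency estimation. Corruption reproduces the
two failure modes of real panels: independent no-calls at `no_call_rate`,
and second mutation events injected at `recurrent_site_rate` (same derived
allele again) or `triallelic_rate` (a third allele) on a clade disjoint
from the marker's true branch, with raw alleles recorded. All draws pass
through one seeded generator: a config reproduces its dataset exactly.

What the simulator does **not** emulate: genotyping error (wrong calls, as
opposed to missing ones), marker ascertainment bias, multi-copy and
deletion markers (simulated markers are substitutions only), and
non-random missingness. Passing tests therefore demonstrate correctness
of the mapping logic under the stated assumptions, not robustness to
miscalls.

## The packaged reference panel

`reference_panel()` encodes, entirely in code, the survey the package
documents itself against: a redrawn Karafet-style backbone of the deepest
MSY clades (revised root: the A1b lineage against everything else), the
printed 22-marker table (real coordinates, parsed from the packaged TSV),
placeholder-named prior markers (prefix `Z` — the branch-by-branch names
of previously reported mutations are not printed anywhere usable), and a
51-chromosome genotype matrix typed in per-haplogroup panels, each with
one ancestral control chromosome from the sibling clade (encoding the
polarity knowledge the discovery sequencing provided — without any
cross-clade ancestral call, every panel-private marker would be
rootward-ambiguous). The fixture manifest (`MANIFEST` /
`fixture/MANIFEST.txt`) lists every reconciliation, including the B-panel
itemization and the collapsed B-M108.1 / B-50f2(P) triangles, which are
excluded from counting as drawn.

## Numerical and formatting choices

* Three-valued calls (`D`/`A`/`N`); a no-call never counts as derived;
  operations needing published ignore-untested logic take
  `policy="observed_only"`.
* Coordinates are 1-based GRCh37, stored as printed; a deletion is one
  binary character with an inclusive coordinate range whose span must
  equal the deleted-sequence length; a multi-copy substitution is one
  character whose paralogous positions are metadata.
* Newick output is deterministic (fixed annotation key order, stored child
  order, no branch lengths), so write → read → write is byte-identical;
  parsing is delegated to dendropy with a package-specific
  `[&key=value]` payload codec.
* Reports sort markers, names and children lexicographically; placement
  order is (derived-set size desc, name), making every pipeline output a
  pure function of its inputs.

## Limitations

No branch lengths or age estimates; no likelihood or Bayesian inference;
no STR/microsatellite support; no genotype-error model; equivalence
classes are claims about the panel, not the population (two markers
equivalent on 51 chromosomes may be separated by the next sample). The
placement engine is greedy (rootward-first) and can leave chromosomes
with heavily missing backbone typing unresolved near the root rather than
guessing; incomplete-matrix perfect phylogeny in full generality is
NP-hard and out of scope.
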