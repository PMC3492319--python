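"""Synthetic genotyping panels with known truth.

The generator emulates the study design the placement pipeline assumes: a
known haplogroup genealogy, a catalog of unique-event markers scattered
on its branches, and a panel of one-to-few representative chromosomes per
lineage typed at those markers.  Sampling is representative, not
population-frequency-based, because the analysis is placement, not
frequency estimation.  Optional corruption reproduces the two failure
modes real panels show: missing calls (independent no-calls at a fixed
rate) and recurrent / triallelic sites (a second mutation event injected
at a clade disjoint from the first, with raw alleles emitted so that
outgroup polarization can untangle it).

All stochastic draws pass through one ``numpy`` generator seeded from the
config, so a config reproduces its dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .genotypes import ANCESTRAL, DERIVED, NO_CALL, GenotypeMatrix, SampleRecord
from .markers import Marker, MarkerCatalog, OutgroupAllele, SUBSTITUTION
from .tree import HaplogroupNode, HaplogroupTree

__all__ = ["SimulationConfig", "simulate_tree_and_markers", "genotype_panel",
           "prune_backbone"]

_NUCS = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    n_leaves: int = 8
    mean_markers_per_branch: float = 3.0
    n_panel_samples: int = 8
    no_call_rate: float = 0.0
    recurrent_site_rate: float = 0.0
    triallelic_rate: float = 0.0
    seed: int = 0
    # guarantees every true branch is detectable; the recovery guarantees
    # of the pipeline only hold when >= 1
    min_markers_per_branch: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1 or self.n_panel_samples < 1:
            raise ValueError("n_leaves and n_panel_samples must be >= 1")
        if self.mean_markers_per_branch <= 0:
            raise ValueError("mean_markers_per_branch must be positive")
        for p in (self.no_call_rate, self.recurrent_site_rate, self.triallelic_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates are probabilities in [0, 1]")


def _random_topology(rng: np.random.Generator, n_leaves: int) -> HaplogroupNode:
    """Random rooted binary shape built by coalescent-style joins."""
    nodes = [
        HaplogroupNode(name=f"L{i + 1}", token=f"L{i + 1}") for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = HaplogroupNode(name=None, children=[nodes[i], nodes[j]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(joined)
    root = HaplogroupNode(name="Root")
    if n_leaves == 1:
        root.children = [nodes[0]]
    else:
        root.children = nodes[0].children
    return root


def simulate_tree_and_markers(
    config: SimulationConfig,
) -> tuple[HaplogroupTree, MarkerCatalog, dict[str, OutgroupAllele]]:
    """Random genealogy plus a marker catalog painted on its branches.

    Each branch receives ``Poisson(mean_markers_per_branch)`` substitution
    markers (at least ``min_markers_per_branch``), with random distinct
    ancestral/derived alleles and synthetic coordinates.  The outgroup
    table carries the root (ancestral) allele of every marker.
    """
    rng = np.random.default_rng(config.seed)
    tree = HaplogroupTree(_random_topology(rng, config.n_leaves))

    catalog = MarkerCatalog()
    outgroup: dict[str, OutgroupAllele] = {}
    counter = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        n_markers = max(
            int(rng.poisson(config.mean_markers_per_branch)),
            config.min_markers_per_branch,
        )
        names = []
        for _ in range(n_markers):
            counter += 1
            name = f"S{counter:04d}"
            anc, der = rng.choice(list(_NUCS), size=2, replace=False)
            catalog.add(
                Marker(
                    name=name,
                    positions=(1000 * counter,),
                    ancestral=str(anc),
                    derived=str(der),
                    mutation_class=SUBSTITUTION,
                    source_tag="simulated",
                )
            )
            outgroup[name] = OutgroupAllele(name, str(anc))
            names.append(name)
        node.markers = sorted(names)
    # name internal nodes deterministically for readable reports
    i = 0
    for node in tree.preorder():
        if node is not tree.root and node.children and node.name is None:
            i += 1
            node.name = f"H{i}"
    return tree, catalog, outgroup


def genotype_panel(
    true_tree: HaplogroupTree,
    catalog: MarkerCatalog,
    config: SimulationConfig,
) -> GenotypeMatrix:
    """Type a representative panel on the true genealogy.

    Samples are assigned to leaves round-robin (sample ``p01`` to the
    first leaf, and so on); each is derived exactly at the markers on its
    root-to-leaf path.  Corruption is then applied in config order:
    recurrent/triallelic second events (raw alleles recorded), then
    independent no-call masking.  ``prior_haplogroup`` of each sample
    records its true leaf.
    """
    rng = np.random.default_rng(config.seed + 1)
    leaves = [n for n in true_tree.preorder() if not n.children]
    pm = true_tree.parent_map()

    path_markers: dict[int, set[str]] = {}
    for leaf in leaves:
        acc: set[str] = set()
        cur: Optional[HaplogroupNode] = leaf
        while cur is not None:
            acc.update(cur.markers)
            cur = pm[id(cur)]
        path_markers[id(leaf)] = acc

    samples = []
    host: dict[str, HaplogroupNode] = {}
    for i in range(config.n_panel_samples):
        leaf = leaves[i % len(leaves)]
        sid = f"p{i + 1:02d}"
        samples.append(SampleRecord(sid, prior_haplogroup=leaf.name))
        host[sid] = leaf

    markers = catalog.names()
    states = {
        s.sample_id: {
            m: (DERIVED if m in path_markers[id(host[s.sample_id])] else ANCESTRAL)
            for m in markers
        }
        for s in samples
    }
    raw = {
        s.sample_id: {
            m: (
                catalog[m].derived
                if states[s.sample_id][m] == DERIVED
                else catalog[m].ancestral
            )
            for m in markers
        }
        for s in samples
    }

    # second events: pick a clade disjoint from the marker's true branch
    branches = [n for n in true_tree.preorder() if n is not true_tree.root]

    def leaf_set(node: HaplogroupNode) -> frozenset[str]:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if not n.children:
                out.add(n.name)
            stack.extend(n.children)
        return frozenset(out)

    for m in markers:
        u = rng.random()
        second_allele: Optional[str] = None
        if u < config.triallelic_rate:
            third = [c for c in _NUCS if c not in (catalog[m].ancestral, catalog[m].derived)]
            second_allele = str(rng.choice(third))
        elif u < config.triallelic_rate + config.recurrent_site_rate:
            second_allele = catalog[m].derived
        if second_allele is None:
            continue
        home = true_tree.find_marker_branch(m)
        home_leaves = leaf_set(home)
        disjoint = [b for b in branches if not (leaf_set(b) & home_leaves)]
        if not disjoint:
            continue
        target = disjoint[int(rng.integers(len(disjoint)))]
        hit = leaf_set(target)
        for s in samples:
            if host[s.sample_id].name in hit:
                states[s.sample_id][m] = DERIVED  # assay sees "not ancestral"
                raw[s.sample_id][m] = second_allele

    if config.no_call_rate > 0:
        for s in samples:
            mask = rng.random(len(markers)) < config.no_call_rate
            for m, hitm in zip(markers, mask):
                if hitm:
                    states[s.sample_id][m] = NO_CALL
                    raw[s.sample_id][m] = ""

    return GenotypeMatrix.from_calls(
        {s.sample_id: states[s.sample_id] for s in samples},
        samples=samples,
        markers=markers,
        raw_alleles={s.sample_id: raw[s.sample_id] for s in samples},
    )


def attach_panel(tree: HaplogroupTree, matrix: GenotypeMatrix) -> HaplogroupTree:
    """Copy of ``tree`` with panel chromosomes at their recorded true leaves."""
    out = tree.copy()
    by_name = {n.name: n for n in out.preorder() if n.name}
    for s in matrix.samples:
        by_name[s.prior_haplogroup].samples.append(s.sample_id)
    return out


def prune_backbone(
    true_tree: HaplogroupTree, rng: np.random.Generator, keep_fraction: float = 0.5
) -> tuple[HaplogroupTree, list[str]]:
    """Contract random internal nodes of the truth into a coarser backbone.

    Returns the backbone and the markers whose branches were contracted
    (these are exactly what placement must rediscover).  Leaves and the
    root's children are kept so the backbone stays a valid tree.
    """
    out = true_tree.copy()
    pm = out.parent_map()
    internal = [
        n
        for n in out.preorder()
        if n.children and n is not out.root and pm[id(n)] is not out.root
    ]
    removed_markers: list[str] = []
    for node in internal:
        if rng.random() < keep_fraction:
            continue
        parent = pm[id(node)]
        idx = parent.children.index(node)
        parent.children = (
            parent.children[:idx] + node.children + parent.children[idx + 1 :]
        )
        parent.samples.extend(node.samples)
        removed_markers.extend(node.markers)
        pm = out.parent_map()
    return out, sorted(removed_markers)
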