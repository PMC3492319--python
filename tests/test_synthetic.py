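"""Panel simulator: determinism, statistical structure, recovery guarantees."""

import numpy as np
import pytest

from msytree import refine
from msytree.genotypes import DERIVED, NO_CALL
from msytree.polarize import detect_multiallelic_sites, polarize_multiallelic
from msytree.simulate import (
    SimulationConfig,
    attach_panel,
    genotype_panel,
    prune_backbone,
    simulate_tree_and_markers,
)
from msytree.tree import write_newick


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_leaves": 0},
            {"mean_markers_per_branch": 0.0},
            {"no_call_rate": 1.5},
            {"triallelic_rate": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestTreeAndMarkers:
    def test_same_seed_gives_identical_output(self):
        cfg = SimulationConfig(n_leaves=7, seed=42)
        t1, c1, o1 = simulate_tree_and_markers(cfg)
        t2, c2, o2 = simulate_tree_and_markers(cfg)
        assert write_newick(t1) == write_newick(t2)
        assert c1 == c2 and o1 == o2

    def test_single_leaf_gives_single_branch_tree(self):
        cfg = SimulationConfig(n_leaves=1, n_panel_samples=1, seed=5,
                               min_markers_per_branch=1)
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        assert len(tree.root.children) == 1
        assert tree.root.children[0].is_leaf()

    def test_poisson_marker_counts_have_the_right_mean(self):
        """Across ~200 branches the empirical mean marker count stays within
        three standard errors of the configured rate."""
        mean = 3.0
        counts = []
        seed = 0
        while len(counts) < 200:
            cfg = SimulationConfig(n_leaves=12, mean_markers_per_branch=mean,
                                   n_panel_samples=12, seed=seed)
            tree, _, _ = simulate_tree_and_markers(cfg)
            counts.extend(
                len(n.markers) for n in tree.preorder() if n is not tree.root
            )
            seed += 1
        counts = np.asarray(counts, dtype=float)
        se = np.sqrt(mean / len(counts))
        assert abs(counts.mean() - mean) < 3 * se

    def test_outgroup_table_carries_root_alleles(self):
        cfg = SimulationConfig(n_leaves=4, seed=9, min_markers_per_branch=1)
        _, catalog, outgroup = simulate_tree_and_markers(cfg)
        for m in catalog:
            assert outgroup[m.name].allele == m.ancestral


class TestGenotypePanel:
    def test_clean_panel_is_perfectly_consistent_with_truth(self):
        cfg = SimulationConfig(n_leaves=6, n_panel_samples=6, seed=11,
                               min_markers_per_branch=1)
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        truth = attach_panel(tree, matrix)
        for m in catalog.names():
            branch = truth.find_marker_branch(m)
            assert matrix.derived_set(m).members == truth.clade_samples(branch)

    def test_no_call_fraction_within_binomial_tolerance(self):
        rate = 0.3
        cfg = SimulationConfig(n_leaves=8, mean_markers_per_branch=3.0,
                               n_panel_samples=12, no_call_rate=rate, seed=13,
                               min_markers_per_branch=1)
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        n_cells = len(matrix.sample_ids) * len(matrix.markers)
        n_missing = sum(
            matrix.state(s, m) == NO_CALL
            for s in matrix.sample_ids
            for m in matrix.markers
        )
        se = np.sqrt(rate * (1 - rate) / n_cells)
        assert abs(n_missing / n_cells - rate) < 4 * se

    def test_triallelic_injection_recovered_as_two_events(self):
        """Every injected triallelic site decomposes into exactly two
        mutation events on complete data (simulator ground truth)."""
        found = 0
        for seed in range(6):
            cfg = SimulationConfig(n_leaves=6, mean_markers_per_branch=2.0,
                                   n_panel_samples=6, seed=seed,
                                   triallelic_rate=0.25, min_markers_per_branch=1)
            tree, catalog, og = simulate_tree_and_markers(cfg)
            matrix = genotype_panel(tree, catalog, cfg)
            truth = attach_panel(tree, matrix)
            for site in detect_multiallelic_sites(matrix, og):
                calls = {s: matrix.raw_allele(s, site) for s in matrix.sample_ids}
                events = polarize_multiallelic(site, calls, og[site], truth)
                assert len(events) == 2
                found += 1
        assert found >= 5, "injection rate should produce multiallelic sites"

    def test_same_seed_gives_identical_matrix(self):
        cfg = SimulationConfig(n_leaves=5, n_panel_samples=7, seed=3,
                               no_call_rate=0.2, min_markers_per_branch=1)
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        m1 = genotype_panel(tree, catalog, cfg)
        m2 = genotype_panel(tree, catalog, cfg)
        assert m1.to_tsv() == m2.to_tsv()


class TestEndToEndGuarantees:
    @pytest.mark.parametrize("seed", range(15))
    def test_complete_data_recovery_and_pruned_branch_reporting(self, seed):
        """Without missing data the pipeline recovers the true tree exactly,
        and the diff against a pruned backbone reports exactly the
        contracted clades."""
        cfg = SimulationConfig(n_leaves=7, mean_markers_per_branch=2.0,
                               n_panel_samples=7, seed=900 + seed,
                               min_markers_per_branch=1)
        tree, catalog, og = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        backbone, _ = prune_backbone(tree, np.random.default_rng(seed))
        res = refine(backbone, matrix, catalog, og)
        truth = attach_panel(tree, matrix)
        assert res.refined.clade_set() == truth.clade_set()
        bb = res.backbone  # backbone with the panel attached
        back_clades = {bb.signature(n) for n in bb.preorder()}
        truth_clades = {truth.signature(n) for n in truth.preorder()}
        refined_clades = {res.refined.signature(n) for n in res.refined.preorder()}
        assert refined_clades - back_clades == truth_clades - back_clades
        assert res.report.n_new_haplogroups == len(truth_clades - back_clades)

    @pytest.mark.parametrize("seed", range(10))
    def test_missing_data_never_contradicts_observed_calls(self, seed):
        """With no-calls, every placed marker still explains all its observed
        calls, and any clade crossing the truth (on chromosomes resolved to
        their true terminal position) is flagged putative."""
        cfg = SimulationConfig(n_leaves=7, mean_markers_per_branch=2.0,
                               n_panel_samples=8, seed=seed, no_call_rate=0.25,
                               min_markers_per_branch=1)
        tree, catalog, og = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        backbone, _ = prune_backbone(tree, np.random.default_rng(seed))
        res = refine(backbone, matrix, catalog, og)
        ref = res.refined
        for n in ref.preorder():
            if n is ref.root:
                continue
            clade = ref.clade_samples(n)
            for m in n.markers:
                if m not in matrix.markers:
                    continue
                ds = matrix.derived_set(m)
                assert not (ds.observed - ds.members) & clade
        truth = attach_panel(tree, matrix)
        putative_nodes = {
            id(p.node) for p in res.placements if p.putative and p.node is not None
        }
        true_leaf = {s.sample_id: s.prior_haplogroup for s in matrix.samples}
        pos = ref.sample_positions()
        resolved = {
            s
            for s, node in pos.items()
            if {t for t in ref.signature(node) if t.startswith("L")}
            == {true_leaf[s]}
        }
        tclades = {
            frozenset(truth.clade_samples(n) & resolved) for n in truth.preorder()
        }
        for n in ref.preorder():
            rc = frozenset(ref.clade_samples(n) & resolved)
            crossing = any(rc & t and not (rc <= t or t <= rc) for t in tclades)
            if crossing:
                assert id(n) in putative_nodes
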