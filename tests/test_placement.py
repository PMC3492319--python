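"""Backbone placement: modes, repositioning, polytomy resolution, flags."""

import numpy as np
import pandas as pd
import pytest

from msytree.genotypes import GenotypeMatrix
from msytree.phylogeny import (
    AMBIGUOUS,
    EXISTING_BRANCH,
    NEW_LEAF_BRANCH,
    ROOT_OF_CLADE,
    SPLIT_BRANCH,
    UNPLACED_INCOMPATIBLE,
    assign_samples,
    audit_backbone_markers,
    equivalence_classes,
    flag_putative,
    place_markers_on_backbone,
    resolve_polytomy,
    write_placement_report,
)
from msytree.simulate import (
    SimulationConfig,
    attach_panel,
    genotype_panel,
    prune_backbone,
    simulate_tree_and_markers,
)
from msytree.tree import read_newick, write_newick


def placements_by_marker(placements):
    return {p.marker: p for p in placements}


@pytest.fixture(scope="module")
def fixture_placements(panel):
    placements, refined = place_markers_on_backbone(panel.backbone, panel.matrix)
    return placements_by_marker(placements), refined


class TestPlacementModes:
    def test_equivalent_marker_joins_existing_branch(self, fixture_placements):
        """V73's derived set matches M114's exactly: same branch, one class."""
        by, refined = fixture_placements
        p = by["V73"]
        assert p.mode == EXISTING_BRANCH
        assert sorted(p.equivalence_class) == ["M114", "V73"]

    def test_marker_joining_two_clades_matches_published_grouping(
        self, fixture_placements
    ):
        """V249, derived across both A2 and A3, lands on the branch that
        already clusters them (equivalence with PK1)."""
        by, _ = fixture_placements
        p = by["V249"]
        assert p.mode == EXISTING_BRANCH
        assert sorted(p.equivalence_class) == ["PK1", "V249"]

    def test_root_of_clade_creates_grouping_node(self, panel):
        """On a backbone lacking the A2+A3 node, a marker derived in both
        clades founds a new internal node joining them."""
        bb = panel.backbone.copy()
        a2t = bb.find("A2-T")
        a23 = bb.find("A2'3")
        a2t.children = [c for c in a2t.children if c is not a23]
        a2t.children[0:0] = a23.children  # splice A2, A3 up; PK1 disappears
        text = panel.matrix.to_tsv()
        df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", dtype=str)
        df = df.drop(columns=["PK1"])
        matrix = GenotypeMatrix.from_tsv(df.to_csv(sep="\t", index=False))
        placements, refined = place_markers_on_backbone(bb, matrix)
        p = placements_by_marker(placements)["V249"]
        assert p.mode == ROOT_OF_CLADE
        assert {c.name for c in p.node.children} == {"A2", "A3"}

    def test_new_terminal_branch_below_named_haplogroup(self, fixture_placements):
        """V218 is derived in one of the two P262 chromosomes only: a new
        terminal branch inside A-P262."""
        by, refined = fixture_placements
        p = by["V218"]
        assert p.mode == NEW_LEAF_BRANCH
        assert refined.clade_samples(p.node) == {"s09"}

    def test_upstream_repositioning_of_published_marker(self, fixture_placements):
        """P289, on one sub-branch in the backbone, is derived in all ten A3
        chromosomes and moves to the branch upstream of both sub-clades."""
        by, refined = fixture_placements
        p = by["P289"]
        assert p.original_branch == "A3a"
        assert p.node is refined.find("A3")

    def test_split_branch_inserts_node_on_basal_edge(self, fixture_placements):
        """The 19 markers shared by all four deep-lineage chromosomes insert
        a node between the root and the P114 terminal."""
        by, refined = fixture_placements
        p = by["V161"]
        assert p.mode == SPLIT_BRANCH
        assert refined.clade_samples(p.node) == {"s01", "s02", "s03", "s04"}

    def test_seven_shared_markers_land_at_macrohaplogroup_root(
        self, fixture_placements
    ):
        """Markers derived in every non-African chromosome join the CT stem."""
        by, refined = fixture_placements
        p = by["Z600"]
        assert p.mode == EXISTING_BRANCH
        assert p.node is refined.find("CT")
        assert {"M168", "M294", "P9.1"} <= set(p.equivalence_class)

    def test_undetermined_position_reported_ambiguous(self, fixture_placements):
        """V248 is derived in the single C2 chromosome: existing C2 branch
        and a private new branch are both consistent."""
        by, refined = fixture_placements
        p = by["V248"]
        assert p.mode == AMBIGUOUS and p.putative
        assert p.node is refined.find("C2")

    def test_incompatible_marker_is_reported_not_forced(self, panel):
        bb = panel.backbone.copy()
        calls = {
            "s04": {"BAD": "D"},   # deep A1b lineage
            "s20": {"BAD": "D"},   # B lineage
            "s33": {"BAD": "A"},   # CT lineage, ancestral: blocks any stem
            "P114": {},
        }
        base = {s: {m: panel.matrix.state(s, m) for m in panel.matrix.markers}
                for s in panel.matrix.sample_ids}
        for s, extra in calls.items():
            if s in base:
                base[s].update(extra)
        matrix = GenotypeMatrix.from_calls(
            base, samples=panel.matrix.samples,
            markers=panel.matrix.markers + ["BAD"],
        )
        placements, _ = place_markers_on_backbone(bb, matrix)
        assert placements_by_marker(placements)["BAD"].mode == UNPLACED_INCOMPATIBLE


class TestSampleAssignmentAndAudit:
    def test_samples_rest_at_deepest_supported_position(self, panel):
        tree = panel.backbone.copy()
        pos = assign_samples(tree, panel.matrix)
        assert pos["s04"].name == "A1b"
        assert pos["s01"].name == "Root"      # ancestral at both basal branches
        assert pos["s29"].name == "B2b"       # derived M112/M192, ancestral below
        assert pos["s33"].name == "DE"

    def test_audit_flags_only_contradicted_markers(self, panel):
        tree = panel.backbone.copy()
        assign_samples(tree, panel.matrix)
        assert audit_backbone_markers(tree, panel.matrix) == ["M112", "P289"]


class TestResolvePolytomy:
    def test_trifurcation_resolved_by_repositioning(self, panel):
        """The B2a/B2b/B2c trifurcation becomes B2a | (B2b, B2c) when M112
        turns out to be derived in the B2c chromosomes as well."""
        tree = panel.backbone.copy()
        assign_samples(tree, panel.matrix)
        b2_before = tree.find("B2")
        assert len(b2_before.children) == 3
        out = resolve_polytomy(tree, "M112", panel.matrix)
        b2 = out.find("B2")
        assert len(b2.children) == 2
        new_node = out.find_marker_branch("M112")
        assert {c.name for c in new_node.children} == {"B2b", "B2c"}

    def test_marker_confined_to_its_child_changes_nothing(self, panel):
        tree = panel.backbone.copy()
        assign_samples(tree, panel.matrix)
        out = resolve_polytomy(tree, "M192", panel.matrix)
        assert write_newick(out) == write_newick(tree)

    def test_marker_covering_all_children_is_rejected(self, panel):
        """Derived in every child of the polytomy: the marker belongs above
        the node, which is placement's business, not repositioning's."""
        from msytree.phylogeny import PhylogenyError

        base = {s: {m: panel.matrix.state(s, m) for m in panel.matrix.markers}
                for s in panel.matrix.sample_ids}
        for i in range(21, 33):  # all B2 chromosomes now derived at M112
            base[f"s{i:02d}"]["M112"] = "D"
        matrix = GenotypeMatrix.from_calls(
            base, samples=panel.matrix.samples, markers=panel.matrix.markers
        )
        tree = panel.backbone.copy()
        assign_samples(tree, matrix)
        with pytest.raises(PhylogenyError, match="above"):
            resolve_polytomy(tree, "M112", matrix)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rebuild_from_scratch_oracle(self, seed):
        """Repositioning inside a synthetic polytomy reproduces the clades a
        full perfect-phylogeny rebuild of the matrix gives."""
        from msytree.phylogeny import build_perfect_phylogeny

        cfg = SimulationConfig(
            n_leaves=6, mean_markers_per_branch=1.5, n_panel_samples=6,
            seed=300 + seed, min_markers_per_branch=1,
        )
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        truth = attach_panel(tree, matrix)
        # contract one internal node to make a polytomy, then hang one of
        # its markers on a child branch (the wrong published position)
        pm = truth.parent_map()
        internal = [
            n for n in truth.preorder()
            if n.children and pm[id(n)] is not None and len(n.markers) >= 1
            and len(n.children) >= 2
        ]
        if not internal:
            pytest.skip("no contractible node in this draw")
        node = internal[0]
        parent = pm[id(node)]
        marker = node.markers[0]
        idx = parent.children.index(node)
        parent.children = (
            parent.children[:idx] + node.children + parent.children[idx + 1:]
        )
        parent.samples.extend(node.samples)
        host = node.children[0]
        host.markers = sorted(host.markers + [marker])
        for m in node.markers[1:]:
            # drop the node's other markers from this exercise
            pass
        resolved = resolve_polytomy(truth, marker, matrix)
        moved = resolved.find_marker_branch(marker)
        want = build_perfect_phylogeny(matrix)
        built_clades = {
            frozenset(want.clade_samples(n)) for n in want.preorder()
        }
        assert frozenset(resolved.clade_samples(moved)) in built_clades


class TestPutativeFlags:
    def test_branches_without_positive_control_are_dashed(self, panel, refined_result):
        refined = refined_result.refined
        dashed = {n.name for n in refined.preorder() if n.putative}
        # no panel chromosome carries these derived: drawn dashed
        assert {"A-P28", "C4", "C6", "C2a", "C3a", "D", "E"} <= dashed

    def test_branches_with_derived_control_are_solid(self, refined_result):
        refined = refined_result.refined
        for name in ("A1b", "A3", "B2", "CT", "C-V20"):
            assert not refined.find(name).putative

    def test_constructed_unsupported_clade_is_flagged(self):
        tree = read_newick("(L1[&markers=m1,token=L1],L2[&markers=m2,token=L2])R;")
        matrix = GenotypeMatrix.from_calls(
            {"a": {"m1": "N", "m2": "A"}, "b": {"m1": "N", "m2": "D"}}
        )
        assign_samples(tree, matrix)
        out = flag_putative(tree, matrix)
        assert out.find("L1").putative
        assert not out.find("L2").putative


class TestPlacementInvariants:
    def test_marker_conservation(self, panel, fixture_placements):
        """Every typed marker ends on exactly one branch or is explicitly
        unplaced; none lost or duplicated."""
        by, refined = fixture_placements
        assert set(by) == set(panel.matrix.markers)
        on_tree = refined.all_markers()
        assert len(on_tree) == len(set(on_tree))
        for marker, p in by.items():
            if p.mode == UNPLACED_INCOMPATIBLE:
                assert marker not in on_tree
            else:
                assert marker in on_tree

    def test_idempotence_of_replacement(self, panel):
        """Re-running placement on the refined tree changes nothing."""
        placements, refined = place_markers_on_backbone(panel.backbone, panel.matrix)
        placements2, refined2 = place_markers_on_backbone(refined, panel.matrix)
        assert write_newick(refined2) == write_newick(refined)
        assert all(p.mode == EXISTING_BRANCH for p in placements2)

    def test_refinement_monotonicity_backbone_clades_preserved(
        self, panel, refined_result
    ):
        bb, refined = refined_result.backbone, refined_result.refined
        ref_sigs = {refined.signature(n) for n in refined.preorder()}
        for node in bb.preorder():
            if node.name or node.markers:
                assert bb.signature(node) in ref_sigs

    @pytest.mark.parametrize("seed", range(10))
    def test_complete_simulation_recovers_true_tree(self, seed):
        cfg = SimulationConfig(
            n_leaves=7, mean_markers_per_branch=2.0, n_panel_samples=7,
            seed=400 + seed, min_markers_per_branch=1,
        )
        tree, catalog, _ = simulate_tree_and_markers(cfg)
        matrix = genotype_panel(tree, catalog, cfg)
        backbone, _ = prune_backbone(tree, np.random.default_rng(seed))
        _, refined = place_markers_on_backbone(backbone, matrix)
        truth = attach_panel(tree, matrix)
        assert refined.clade_set() == truth.clade_set()


def test_placement_report_is_tabular(refined_result):
    text = write_placement_report(refined_result.placements)
    lines = text.strip().split("\n")
    assert lines[0].startswith("marker\tmode\ttarget")
    assert len(lines) == len(refined_result.placements) + 1
    v73 = next(l for l in lines if l.startswith("V73\t"))
    assert "existing_branch" in v73 and "M114" in v73
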