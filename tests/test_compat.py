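"""Directed character compatibility and perfect-phylogeny construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msytree.genotypes import DerivedSet, GenotypeMatrix
from msytree.phylogeny import (
    IncompatibleMarkersError,
    PhylogenyError,
    are_compatible,
    build_perfect_phylogeny,
)
from msytree.simulate import SimulationConfig, genotype_panel, simulate_tree_and_markers

from conftest import enumerate_clade_families


def ds(name, members, observed):
    return DerivedSet(name, frozenset(members), frozenset(observed))


UNIVERSE = set("abcdef")


class TestAreCompatible:
    def test_nested_sets_are_compatible(self):
        assert are_compatible(ds("x", "ab", UNIVERSE), ds("y", "abc", UNIVERSE))

    def test_overlapping_non_nested_are_incompatible(self):
        assert not are_compatible(ds("x", "ab", UNIVERSE), ds("y", "bc", UNIVERSE))

    def test_disjoint_sets_are_compatible(self):
        assert are_compatible(ds("x", "ab", UNIVERSE), ds("y", "cd", UNIVERSE))

    def test_restriction_to_jointly_observed(self):
        # x and y would cross on chromosome c, but c is unobserved for x:
        # on the jointly observed set they are nested, hence compatible
        a = ds("x", "ab", UNIVERSE - {"c"})
        b = ds("y", "bc", UNIVERSE)
        assert not are_compatible(ds("x", "ab", UNIVERSE), b)
        assert are_compatible(a, b)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sets(st.sampled_from(sorted(UNIVERSE))),
        st.sets(st.sampled_from(sorted(UNIVERSE))),
    )
    def test_matches_two_gamete_enumeration(self, ma, mb):
        """Directed characters conflict iff the three gametes (1,1), (1,0),
        (0,1) all occur among jointly observed chromosomes."""
        a, b = ds("a", ma, UNIVERSE), ds("b", mb, UNIVERSE)
        both = ma & mb
        only_a = ma - mb
        only_b = mb - ma
        expected = not (both and only_a and only_b)
        assert are_compatible(a, b) == expected


def complete_sim_matrix(seed, n_leaves, max_markers=15):
    cfg = SimulationConfig(
        n_leaves=n_leaves,
        mean_markers_per_branch=1.2,
        n_panel_samples=n_leaves,
        seed=seed,
        min_markers_per_branch=1,
    )
    tree, catalog, _ = simulate_tree_and_markers(cfg)
    matrix = genotype_panel(tree, catalog, cfg)
    keep = matrix.markers[:max_markers]
    states = {s: {m: matrix.state(s, m) for m in keep} for s in matrix.sample_ids}
    return GenotypeMatrix.from_calls(states, samples=matrix.samples, markers=keep)


def tree_clades(tree):
    out = set()
    for node in tree.preorder():
        c = tree.clade_samples(node)
        if c:
            out.add(frozenset(c))
    return frozenset(out)


def minimal_family_closed_form(matrix):
    """Independent containment-order oracle: the minimal realizing clade set
    is exactly {derived sets} + {singletons} + {universe}."""
    fam = {frozenset([s]) for s in matrix.sample_ids}
    fam.add(frozenset(matrix.sample_ids))
    for m in matrix.markers:
        members = matrix.derived_set(m).members
        if members:
            fam.add(frozenset(members))
    return frozenset(fam)


class TestBuildPerfectPhylogeny:
    def test_single_sample_all_derived_is_single_branch(self):
        m = GenotypeMatrix.from_calls({"a": {"X": "D", "Y": "D", "Z": "D"}})
        tree = build_perfect_phylogeny(m)
        assert len(tree.root.children) == 1
        branch = tree.root.children[0]
        assert sorted(branch.markers) == ["X", "Y", "Z"]
        assert branch.samples == ["a"]

    def test_two_sample_split_with_shared_stem(self, panel):
        """Two chromosomes sharing 19 of 23 derived markers: a stem branch
        with the shared 19 and two terminal branches carrying the rest."""
        spec = panel.panels["A1a"]
        states = {
            s: {m: panel.matrix.state(s, m) for m in spec.markers}
            for s in spec.samples
        }
        m = GenotypeMatrix.from_calls(states, markers=spec.markers)
        tree = build_perfect_phylogeny(m)
        stem = tree.root.children[0]
        assert len(stem.markers) == 19
        leaves = [n for n in tree.preorder() if n.is_leaf()]
        assert len(leaves) == 2
        assert sorted(len(l.markers) for l in leaves) == [0, 4]

    def test_rejects_incomplete_matrix(self):
        m = GenotypeMatrix.from_calls({"a": {"X": "D"}, "b": {"X": "N"}})
        with pytest.raises(PhylogenyError, match="no-call"):
            build_perfect_phylogeny(m)

    def test_incompatible_pair_named_in_error(self):
        m = GenotypeMatrix.from_calls(
            {
                "a": {"X": "D", "Y": "A"},
                "b": {"X": "D", "Y": "D"},
                "c": {"X": "A", "Y": "D"},
            }
        )
        with pytest.raises(IncompatibleMarkersError) as exc:
            build_perfect_phylogeny(m)
        assert exc.value.pair == ("X", "Y")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_small_tree_search(self, seed):
        """On complete compatible matrices (<=6 leaves) the builder's clades
        equal those of the unique minimal realizing tree found by brute
        force over all rooted topologies."""
        matrix = complete_sim_matrix(seed, n_leaves=2 + seed % 5)
        built = tree_clades(build_perfect_phylogeny(matrix))
        leaves = tuple(sorted(matrix.sample_ids))
        derived = {
            frozenset(matrix.derived_set(m).members)
            for m in matrix.markers
            if matrix.derived_set(m).members
        }
        realizing = [
            fam for fam in enumerate_clade_families(leaves) if derived <= fam
        ]
        assert realizing, "simulated matrix must be realizable"
        best = min(len(f) for f in realizing)
        minimal = {f for f in realizing if len(f) == best}
        assert len(minimal) == 1, "minimal realizing tree must be unique"
        assert built == next(iter(minimal))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_containment_order_oracle(self, seed):
        matrix = complete_sim_matrix(1000 + seed, n_leaves=4 + seed % 5)
        built = tree_clades(build_perfect_phylogeny(matrix))
        assert built == minimal_family_closed_form(matrix)

    def test_equivalent_markers_share_a_branch(self):
        m = GenotypeMatrix.from_calls(
            {
                "a": {"X": "D", "Y": "D", "Z": "A"},
                "b": {"X": "D", "Y": "D", "Z": "A"},
                "c": {"X": "A", "Y": "A", "Z": "D"},
            }
        )
        tree = build_perfect_phylogeny(m)
        branch = tree.find_marker_branch("X")
        assert sorted(branch.markers) == ["X", "Y"]


@pytest.mark.parametrize("seed", range(10))
def test_compatibility_theorem_both_directions(seed):
    """A perfect phylogeny exists iff all marker pairs are compatible."""
    rng = np.random.default_rng(seed)
    n, k = 6, 8
    sids = [f"p{i}" for i in range(n)]
    states = {
        s: {f"S{j}": ("D" if rng.random() < 0.4 else "A") for j in range(k)}
        for s in sids
    }
    matrix = GenotypeMatrix.from_calls(states)
    sets = [matrix.derived_set(m) for m in matrix.markers]
    all_ok = all(
        are_compatible(a, b) for i, a in enumerate(sets) for b in sets[i + 1 :]
    )
    if all_ok:
        tree = build_perfect_phylogeny(matrix)
        clades = tree_clades(tree)
        for s in sets:
            if s.members:
                assert frozenset(s.members) in clades
    else:
        with pytest.raises(IncompatibleMarkersError):
            build_perfect_phylogeny(matrix)
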