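"""Tree engine: NJ correctness, bootstrap behaviour, tree queries."""

import itertools

import numpy as np
import pytest

from mosaicscreen.errors import (ConfigError, InvalidMatrixError,
                                 InvalidTaxaSetError, UnknownTaxonError)
from mosaicscreen.msa import Alignment
from mosaicscreen.trees import (bootstrap_supports,
                                collapse_single_genus_clades,
                                distances_from_leaf, neighbor_joining,
                                patristic_distance, read_newick,
                                reroot_on_clade, set_all_supports,
                                supported_bipartition, write_newick)

from conftest import (oracle_bipartitions, oracle_distance_matrix,
                      random_binary_topology)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_two_taxa_single_edge_of_total_length(self):
        pt = neighbor_joining((["A_a", "B_b"], np.array([[0, 0.4], [0.4, 0]])))
        assert patristic_distance(pt, "A_a", "B_b") == pytest.approx(0.4)

    def test_three_taxa_closed_form_pendant_lengths(self):
        d = {("A", "B"): 0.3, ("A", "C"): 0.5, ("B", "C"): 0.6}
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        pt = neighbor_joining((["A_a", "B_b", "C_c"], m))
        dists = distances_from_leaf(pt, "A_a")
        a = (d[("A", "B")] + d[("A", "C")] - d[("B", "C")]) / 2
        b = d[("A", "B")] - a
        c = d[("A", "C")] - a
        assert dists["B_b"] == pytest.approx(a + b)
        assert dists["C_c"] == pytest.approx(a + c)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> hand-computed path lengths
        labels = ["A_a", "B_b", "C_c", "D_d"]
        m = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        pt = neighbor_joining((labels, m))
        assert set(pt.bipartition_supports()) == {frozenset({"C_c", "D_d"})}
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert patristic_distance(pt, a, b) == pytest.approx(m[i, j])

    @pytest.mark.parametrize("seed", range(25))
    def test_nj_is_exact_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = [f"T_{i:02d}" for i in range(n)]
        root = random_binary_topology(rng, labels)
        order, matrix = oracle_distance_matrix(root)
        pt = neighbor_joining((order, matrix))
        assert set(pt.bipartition_supports()) == oracle_bipartitions(root)
        for a, b in itertools.combinations(order, 2):
            i, j = order.index(a), order.index(b)
            assert abs(patristic_distance(pt, a, b) - matrix[i, j]) < 1e-9

    def test_agrees_with_skbio_on_generic_matrices(self):
        # independent implementation cross-check on non-additive input
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 8
            coords = rng.uniform(size=(n, 4))
            m = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            labels = [f"T_{i}" for i in range(n)]
            ours = neighbor_joining((labels, m))
            theirs = skbio_nj(DistanceMatrix(m, ids=labels))
            ours_splits = set(ours.bipartition_supports())
            theirs_pt = read_newick(str(theirs))
            assert set(theirs_pt.bipartition_supports()) == ours_splits

    def test_negative_estimates_are_clamped_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = rng.uniform(0.05, 2.0, size=(6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            pt = neighbor_joining(([f"T_{i}" for i in range(6)], m))
            for node in pt.tree.preorder_node_iter():
                if node.edge.length is not None:
                    assert node.edge.length >= 0.0

    def test_invalid_matrices_are_rejected(self):
        with pytest.raises(InvalidMatrixError):
            neighbor_joining((["A", "B"], np.array([[0, np.nan], [np.nan, 0]])))
        with pytest.raises(InvalidMatrixError):
            neighbor_joining((["A", "B", "C"],
                              np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _four_clade_alignment(seed=0, length=300, scramble=False):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    base = rng.integers(0, 20, length)

    def mutate(seq, n):
        s = seq.copy()
        idx = rng.choice(len(s), n, replace=False)
        s[idx] = (s[idx] + rng.integers(1, 20, n)) % 20
        return s

    left, right = mutate(base, 120), mutate(base, 180)
    rows = [("Clade1_a", mutate(left, 6)), ("Clade1_b", mutate(left, 6)),
            ("Clade2_a", mutate(right, 6)), ("Clade2_b", mutate(right, 6))]
    if scramble:
        rows = rows[::-1]
    return Alignment.from_records(
        [(name, "".join(aa[i] for i in seq)) for name, seq in rows])


class TestBootstrap:
    def test_clean_split_gets_full_support(self):
        pt = bootstrap_supports(_four_clade_alignment(), 100, seed=11)
        supports = pt.bipartition_supports()
        assert supports[frozenset({"Clade2_a", "Clade2_b"})] == 100.0

    def test_supports_are_percentages_and_deterministic(self):
        a = bootstrap_supports(_four_clade_alignment(), 50, seed=5)
        b = bootstrap_supports(_four_clade_alignment(), 50, seed=5)
        assert write_newick(a) == write_newick(b)
        for support in a.bipartition_supports().values():
            assert 0.0 <= support <= 100.0

    def test_supports_invariant_under_row_order(self):
        a = bootstrap_supports(_four_clade_alignment(), 50, seed=5)
        b = bootstrap_supports(_four_clade_alignment(scramble=True), 50, seed=5)
        assert a.bipartition_supports() == b.bipartition_supports()

    def test_zero_replicates_is_a_config_error(self):
        with pytest.raises(ConfigError):
            bootstrap_supports(_four_clade_alignment(), 0)


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

class TestPatristic:
    tree = "((A_a:1,B_b:2):1,(C_c:3,D_d:4));"

    def test_distance_to_self_is_zero(self):
        pt = read_newick(self.tree)
        assert patristic_distance(pt, "A_a", "A_a") == 0.0

    def test_hand_computed_path_sum(self):
        pt = read_newick(self.tree)
        assert patristic_distance(pt, "A_a", "C_c") == pytest.approx(5.0)

    def test_symmetry_and_unknown_leaf(self):
        pt = read_newick(self.tree)
        assert (patristic_distance(pt, "A_a", "D_d")
                == patristic_distance(pt, "D_d", "A_a"))
        with pytest.raises(UnknownTaxonError):
            patristic_distance(pt, "A_a", "Zz_z")

    @pytest.mark.parametrize("seed", range(8))
    def test_four_point_condition_holds_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"T_{i}" for i in range(8)]
        root = random_binary_topology(rng, labels)
        order, matrix = oracle_distance_matrix(root)
        pt = neighbor_joining((order, matrix))
        for quartet in itertools.combinations(order, 4):
            a, b, c, d = quartet
            sums = sorted([
                patristic_distance(pt, a, b) + patristic_distance(pt, c, d),
                patristic_distance(pt, a, c) + patristic_distance(pt, b, d),
                patristic_distance(pt, a, d) + patristic_distance(pt, b, c)])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)


# ---------------------------------------------------------------------------
# Single-genus collapsing
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_cherry_of_one_genus_keeps_one_representative(self, taxonomy):
        s = ("((Ostreococcus_tauri:1,Ostreococcus_lucimarinus:1):1,"
             "((Euglena_gracilis:1,Galdieria_sulphuraria:1):1,"
             "Micromonas_pusilla:2));")
        pt = collapse_single_genus_clades(read_newick(s), taxonomy,
                                          protected={"Euglena_gracilis"})
        leaves = set(pt.leaf_labels())
        assert sum(l.startswith("Ostreococcus") for l in leaves) == 1
        assert "Ostreococcus_lucimarinus" in leaves  # lexicographic keep

    def test_genus_mixed_tree_is_unchanged(self, taxonomy):
        s = ("((Euglena_gracilis:1,Galdieria_sulphuraria:1):1,"
             "Micromonas_pusilla:1,Porphyra_yezoensis:1);")
        pt = collapse_single_genus_clades(read_newick(s), taxonomy,
                                          protected={"Euglena_gracilis"})
        assert sorted(pt.leaf_labels()) == [
            "Euglena_gracilis", "Galdieria_sulphuraria",
            "Micromonas_pusilla", "Porphyra_yezoensis"]

    def test_nested_single_genus_clade_collapses_parent_untouched(self, taxonomy):
        # three Ostreococcus/Micromonas-style leaves inside a mixed clade
        s = ("((Euglena_gracilis:1,Galdieria_sulphuraria:1):1,"
             "(((Ostreococcus_tauri:1,Ostreococcus_lucimarinus:1):1,"
             "Porphyra_yezoensis:1):1,Micromonas_pusilla:1));")
        pt = collapse_single_genus_clades(read_newick(s), taxonomy,
                                          protected={"Euglena_gracilis"})
        leaves = set(pt.leaf_labels())
        assert sum(l.startswith("Ostreococcus") for l in leaves) == 1
        assert {"Porphyra_yezoensis", "Micromonas_pusilla"} <= leaves

    def test_protected_leaves_never_pruned(self, taxonomy):
        s = ("((Euglena_gracilis:1,Eutreptiella_gymnastica:1):1,"
             "(Galdieria_sulphuraria:1,Porphyra_yezoensis:1):1,"
             "Micromonas_pusilla:1);")
        pt = collapse_single_genus_clades(read_newick(s), taxonomy,
                                          protected={"Euglena_gracilis"})
        assert "Euglena_gracilis" in pt.leaf_labels()

    def test_bipartitions_restrict_to_output_leafset(self, taxonomy):
        s = ("(((Ostreococcus_tauri:1,Ostreococcus_lucimarinus:1):1,"
             "(Galdieria_sulphuraria:1,Cyanidioschyzon_merolae:1):1):1,"
             "(Euglena_gracilis:1,(Micromonas_pusilla:1,Porphyra_yezoensis:1):1));")
        before = read_newick(s)
        after = collapse_single_genus_clades(before, taxonomy,
                                             protected={"Euglena_gracilis"})
        kept = frozenset(after.leaf_labels())
        assert kept <= frozenset(before.leaf_labels())
        n = len(kept)
        restricted = set()
        for side in before.bipartition_supports():
            s2 = frozenset(side) & kept
            if 2 <= len(s2) <= n - 2:
                comp = kept - s2
                restricted.add(min(s2, comp, key=sorted))
        out_splits = {min(side, kept - side, key=sorted)
                      for side in after.bipartition_supports()}
        assert out_splits <= restricted

    def test_patristic_distances_preserved_for_kept_leaves(self, taxonomy):
        s = ("((Ostreococcus_tauri:1,Ostreococcus_lucimarinus:1):1,"
             "((Euglena_gracilis:2,Galdieria_sulphuraria:1):1,"
             "Micromonas_pusilla:2));")
        before = read_newick(s)
        after = collapse_single_genus_clades(before, taxonomy,
                                             protected={"Euglena_gracilis"})
        for leaf in after.leaf_labels():
            if leaf != "Euglena_gracilis":
                assert (patristic_distance(after, "Euglena_gracilis", leaf)
                        == pytest.approx(patristic_distance(
                            before, "Euglena_gracilis", leaf)))


# ---------------------------------------------------------------------------
# Supported bipartitions & rerooting
# ---------------------------------------------------------------------------

class TestSupportedBipartition:
    tree = "((A_x:1,B_y:2)70:1,(C_z:3,D_w:4)65:2,E_v:5);"

    def test_singleton_is_trivially_present(self):
        pt = read_newick(self.tree)
        assert supported_bipartition(pt, {"E_v"}, 70) == "present"

    def test_support_at_threshold_is_inclusive(self):
        pt = read_newick(self.tree)
        assert supported_bipartition(pt, {"A_x", "B_y"}, 70) == "present"

    def test_below_threshold_is_present_unsupported(self):
        pt = read_newick(self.tree)
        assert supported_bipartition(pt, {"C_z", "D_w"}, 70) == "present_unsupported"

    def test_missing_split_is_absent(self):
        pt = read_newick(self.tree)
        assert supported_bipartition(pt, {"A_x", "C_z"}, 0) == "absent"

    def test_non_proper_subsets_are_rejected(self):
        pt = read_newick(self.tree)
        with pytest.raises(InvalidTaxaSetError):
            supported_bipartition(pt, set(), 70)
        with pytest.raises(InvalidTaxaSetError):
            supported_bipartition(pt, {"A_x", "B_y", "C_z", "D_w", "E_v"}, 70)


def test_newick_round_trip_is_stable():
    s = "((A_x:1,B_y:2)90:1,(C_z:3,D_w:4)80:2,E_v:5);"
    once = write_newick(read_newick(s))
    assert write_newick(read_newick(once)) == once


def test_reroot_preserves_supports_and_distances():
    s = "((A_x:1,B_y:2)90:1,(C_z:3,D_w:4)80:2,E_v:5);"
    pt = read_newick(s)
    rooted = reroot_on_clade(pt, {"E_v"})
    assert rooted.is_rooted()
    assert rooted.bipartition_supports() == pt.bipartition_supports()
    for a, b in itertools.combinations(pt.leaf_labels(), 2):
        assert (patristic_distance(rooted, a, b)
                == pytest.approx(patristic_distance(pt, a, b)))


def test_set_all_supports_touches_every_internal_edge():
    s = "((A_x:1,B_y:2)90:1,(C_z:3,D_w:4):2,E_v:5);"
    pt = set_all_supports(read_newick(s), 42.0)
    assert set(pt.bipartition_supports().values()) == {42.0}
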