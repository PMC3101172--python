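"""Alignment processing: trimming, distances, shared-indel diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaicscreen.errors import (EmptyAlignmentError, InvalidCandidateSetError,
                                 NoOverlapError, QueryTooGappyError,
                                 TooFewTaxaError)
from mosaicscreen.msa import (Alignment, SATURATION_P, drop_gappy_taxa,
                              find_shared_indels, pairwise_distance,
                              read_fasta, trim_gappy_columns, write_fasta)


def aln_of(*rows):
    return Alignment.from_records(
        [(f"Taxon_{chr(97 + i)}", seq) for i, seq in enumerate(rows)])


# ---------------------------------------------------------------------------
# Column / taxon trimming
# ---------------------------------------------------------------------------

class TestTrimGappyColumns:
    def test_gapless_alignment_is_untouched(self):
        aln = aln_of("MKVALSTAGA", "MKVALSTAGA", "MRVALSVAGA", "MKVALSVAGA")
        assert trim_gappy_columns(aln, 0.5) is aln

    def test_column_over_threshold_is_removed(self):
        # column 2 has 3/4 gaps (0.75 > 0.5); every other column kept
        aln = aln_of("MK-ALSTAGA", "MK-ALSTAGA", "MR-ALSVAGA", "MKVALSVAGA")
        out = trim_gappy_columns(aln, 0.5)
        assert out.n_cols == 9
        assert out.sequence("Taxon_d") == "MKALSVAGA"

    def test_threshold_one_keeps_everything(self):
        aln = aln_of("M-", "M-", "MK", "MK")
        assert trim_gappy_columns(aln, 1.0).n_cols == 2

    def test_all_columns_removed_is_an_error(self):
        aln = aln_of("--", "--", "-K", "MK")
        with pytest.raises(EmptyAlignmentError):
            trim_gappy_columns(aln, 0.2)

    @given(st.lists(st.lists(st.sampled_from("ACDEF-"), min_size=8, max_size=8)
                    .map("".join), min_size=4, max_size=8),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_trimming_is_idempotent(self, rows, threshold):
        aln = aln_of(*rows)
        try:
            once = trim_gappy_columns(aln, threshold)
        except EmptyAlignmentError:
            return
        twice = trim_gappy_columns(once, threshold)
        assert list(once.rows()) == list(twice.rows())


class TestDropGappyTaxa:
    def test_no_row_over_threshold_is_identity(self):
        aln = aln_of("MKVALSTAGA", "MKVALSTAGA", "MRVALSVAGA", "MKVALSVAGA")
        assert drop_gappy_taxa(aln, 0.75) is aln

    def test_gap_rich_row_is_dropped(self):
        aln = aln_of("M---------", "MKVALSTAGA", "MRVALSVAGA", "MKVALSVAGA",
                     "MKVALSVAGC")
        out = drop_gappy_taxa(aln, 0.8)
        assert "Taxon_a" not in out.ids and out.n_rows == 4

    def test_query_over_threshold_rejects_the_gene(self):
        aln = aln_of("M---------", "MKVALSTAGA", "MRVALSVAGA", "MKVALSVAGA")
        with pytest.raises(QueryTooGappyError):
            drop_gappy_taxa(aln, 0.8, query="Taxon_a")

    def test_dropping_below_four_taxa_is_an_error(self):
        aln = aln_of("M---------", "M---------", "MRVALSVAGA", "MKVALSVAGA")
        with pytest.raises(TooFewTaxaError):
            drop_gappy_taxa(aln, 0.8)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class TestPairwiseDistance:
    def test_identical_sequences_are_at_zero_under_both_models(self):
        aln = aln_of("MKVALSTAGA", "MKVALSTAGA")
        for model in ("p_distance", "poisson"):
            assert pairwise_distance(aln, model)[0, 1] == 0.0

    def test_p_distance_counts_mismatches_over_comparable_columns(self):
        aln = aln_of("AAAAACCCCC", "AAAAADDDDD")  # 5 of 10 differ
        assert pairwise_distance(aln, "p_distance")[0, 1] == 0.5

    def test_gaps_and_x_are_excluded_from_comparable_columns(self):
        aln = aln_of("AA-XC", "AAAAC")  # comparable: cols 0,1,4; 0 mismatches
        assert pairwise_distance(aln, "p_distance")[0, 1] == 0.0

    def test_poisson_correction_of_known_p(self):
        aln = aln_of("AAAAACCCCC", "AAAAADDDDD")
        d = pairwise_distance(aln, "poisson")[0, 1]
        assert d == pytest.approx(-math.log(0.5))

    def test_saturated_pairs_are_capped_not_infinite(self):
        aln = aln_of("AAAAAAAAAA", "CCCCCCCCCC")  # p = 1.0
        d = pairwise_distance(aln, "poisson")[0, 1]
        assert d == pytest.approx(-math.log(1 - SATURATION_P))

    def test_no_overlap_names_the_offending_pair(self):
        aln = aln_of("AA---", "---CC", "AACCC")
        with pytest.raises(NoOverlapError) as err:
            pairwise_distance(aln)
        assert err.value.pair == ("Taxon_a", "Taxon_b")

    @given(st.lists(st.lists(st.sampled_from("ACDE"), min_size=6, max_size=6)
                    .map("".join), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_in_unit_interval_and_poisson_dominates(self, rows):
        aln = aln_of(*rows)
        p = np.asarray(pairwise_distance(aln, "p_distance").data)
        poisson = np.asarray(pairwise_distance(aln, "poisson").data)
        assert ((p >= 0) & (p <= 1)).all()
        assert (poisson >= p - 1e-12).all()
        # zero iff identical on comparable columns
        assert ((p == 0) == (poisson == 0)).all()


# ---------------------------------------------------------------------------
# Shared indels
# ---------------------------------------------------------------------------

class TestFindSharedIndels:
    def test_gapless_alignment_has_no_signatures(self):
        aln = aln_of("MKVAL", "MKVAL", "MRVAL")
        assert find_shared_indels(aln, 1, {"Taxon_a"}) == []

    def test_deletion_block_spanning_candidate_rows(self):
        aln = aln_of("MK---STAGA", "MK---STAGA", "MKVALSVAGA", "MKVALSVAGA")
        sigs = find_shared_indels(aln, 3, {"Taxon_a", "Taxon_b"})
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.start_col, sig.end_col, sig.state) == (2, 5, "deletion_block")

    def test_insertion_block_is_the_converse(self):
        aln = aln_of("MKQQQSTAGA", "MKQWQSTAGA", "MK---STAGA", "MK---STAGA")
        sigs = find_shared_indels(aln, 3, {"Taxon_a", "Taxon_b"})
        assert [s.state for s in sigs] == ["insertion_block"]

    def test_universal_gap_column_is_not_discriminative(self):
        aln = aln_of("MK-AL", "MK-AL", "MK-AL")
        assert find_shared_indels(aln, 1, {"Taxon_a"}) == []

    def test_runs_shorter_than_min_len_are_ignored(self):
        aln = aln_of("MK--LSTAGA", "MK--LSTAGA", "MKVALSVAGA", "MKVALSVAGA")
        assert find_shared_indels(aln, 3, {"Taxon_a", "Taxon_b"}) == []

    def test_intervals_are_maximal_and_disjoint(self):
        aln = aln_of("M--AL--AGA", "M--AL--AGA", "MKVALSVAGA", "MKVALSVAGA")
        sigs = find_shared_indels(aln, 2, {"Taxon_a", "Taxon_b"})
        intervals = [(s.start_col, s.end_col) for s in sigs]
        assert intervals == [(1, 3), (5, 7)]
        gap = aln.gap_mask()
        for start, end in intervals:  # extending either endpoint breaks it
            for col in (start - 1, end):
                carriers_gap = gap[:2, col].all()
                rest_clean = ~gap[2:, col].any()
                assert not (carriers_gap and rest_clean)

    @pytest.mark.parametrize("candidates", [set(), {"Taxon_zz"},
                                            {"Taxon_a", "Taxon_b", "Taxon_c"}])
    def test_degenerate_candidate_sets_are_rejected(self, candidates):
        aln = aln_of("MKVAL", "MKVAL", "MRVAL")
        with pytest.raises(InvalidCandidateSetError):
            find_shared_indels(aln, 1, candidates)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def test_fasta_round_trip_preserves_order_and_residues(tmp_path):
    aln = aln_of("MKV-LSTAGA" * 10, "MKVALSTAGA" * 10, "MRVALSVAGA" * 10)
    path = tmp_path / "aln.fasta"
    write_fasta(aln, str(path))
    back = read_fasta(str(path))
    assert list(back.rows()) == list(aln.rows())
    # wrapped at 60 columns
    body = [l for l in path.read_text().splitlines() if not l.startswith(">")]
    assert max(len(l) for l in body) == 60
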