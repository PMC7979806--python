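"""Aligner correctness, alignment IO, correspondence mapping, conservation calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from Bio.Align import substitution_matrices

from pikkmap.conservation import (
    AlignedPair,
    AlignParams,
    call_conserved,
    correspondence,
    global_align,
    hr_block_alignment,
    identity_report,
    map_residue,
    pair_from_alignment,
    percent_identity,
    read_alignment,
)
from pikkmap.synthetic import OrthologSpec, random_protein, simulate_ortholog

from oracles import brute_force_align_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")
PARAMS = AlignParams()
aa_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=6)


class TestGlobalAlign:
    def test_self_alignment_is_all_match_columns(self):
        pair = global_align("ACDE", "ACDE")
        assert pair.row_a == "ACDE" and pair.row_b == "ACDE"
        assert pair.score == sum(BLOSUM62[c, c] for c in "ACDE")

    def test_affine_gap_run_cost(self):
        # one gap run of length 2: two matches minus open minus one extend
        pair = global_align("AAAA", "AA")
        assert pair.score == 2 * BLOSUM62["A", "A"] - 10 - 1
        assert pair.row_b.count("-") == 2

    def test_ungapping_recovers_inputs(self):
        pair = global_align("MKWVTFISLL", "MKWTFSLL")
        assert pair.seq_a == "MKWVTFISLL"
        assert pair.seq_b == "MKWTFSLL"

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            global_align("AC1E", "ACDE")

    def test_deterministic_for_fixed_inputs(self):
        p1 = global_align("GATTACA", "GCATGCT")
        p2 = global_align("GATTACA", "GCATGCT")
        assert (p1.row_a, p1.row_b, p1.score) == (p2.row_a, p2.row_b, p2.score)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(aa_seq, aa_seq)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        pair = global_align(a, b)
        expected = brute_force_align_score(
            a, b, BLOSUM62, PARAMS.gap_open, PARAMS.gap_extend
        )
        assert pair.score == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(aa_seq, aa_seq)
    def test_alignment_rows_rescore_to_reported_score(self, a, b):
        """The emitted alignment itself must achieve the reported score."""
        pair = global_align(a, b)
        score, run = 0.0, None
        for ca, cb in zip(pair.row_a, pair.row_b):
            if ca != "-" and cb != "-":
                score += BLOSUM62[ca, cb]
                run = None
            else:
                gap = "a" if ca == "-" else "b"
                score -= PARAMS.gap_extend if run == gap else PARAMS.gap_open
                run = gap
        assert score == pair.score


class TestAlignmentIO:
    def test_two_row_fasta(self, tmp_path):
        path = tmp_path / "pair.afa"
        path.write_text(">human\nAC-E\n>yeast\nACDE\n")
        pair = read_alignment(path)
        assert isinstance(pair, AlignedPair)
        assert pair.row_a == "AC-E" and pair.id_b == "yeast"

    def test_clustal_blocks_are_concatenated(self, tmp_path):
        path = tmp_path / "aln.aln"
        path.write_text(
            "CLUSTAL W multiple sequence alignment\n\n"
            "human      ACDEF\n"
            "yeast      ACD-F\n\n"
            "human      GHIKL\n"
            "yeast      GH-KL\n"
        )
        pair = read_alignment(path, format="clustal")
        assert pair.row_a == "ACDEFGHIKL"
        assert pair.row_b == "ACD-FGH-KL"

    def test_ragged_rows_error(self, tmp_path):
        path = tmp_path / "ragged.afa"
        path.write_text(">a\nACDE\n>b\nAC\n")
        with pytest.raises(ValueError):
            read_alignment(path)

    def test_duplicate_ids_error(self, tmp_path):
        path = tmp_path / "dup.afa"
        path.write_text(">a\nACDE\n>a\nACDE\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_alignment(path)

    def test_multi_row_and_pair_extraction(self, tmp_path):
        path = tmp_path / "msa.afa"
        path.write_text(">h\nACDE\n>m\nACDE\n>y\nAC-E\n")
        msa = read_alignment(path)
        pair = pair_from_alignment(msa, "h", "y")
        assert pair.row_b == "AC-E"


class TestPercentIdentity:
    def test_self_alignment_is_100(self):
        pair = global_align("MKWVTF", "MKWVTF")
        assert percent_identity(pair) == 100.0

    def test_columns_convention(self):
        pair = AlignedPair("a", "b", "AC-E", "ACDE")
        assert percent_identity(pair, "columns") == 75.0
        assert percent_identity(pair, "shorter_seq") == 100.0
        report = identity_report(pair)
        assert report["identity_pct_columns"] == 75.0

    def test_symmetric_in_arguments(self):
        pair = AlignedPair("a", "b", "AC-EF", "ACD-F")
        swapped = AlignedPair("b", "a", pair.row_b, pair.row_a)
        for conv in ("columns", "shorter_seq"):
            assert percent_identity(pair, conv) == percent_identity(swapped, conv)

    def test_self_score_is_maximal(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            assert global_align(seq, seq).score >= global_align(seq, other).score


class TestCorrespondence:
    def test_identity_alignment_maps_i_to_i(self):
        corr = correspondence(AlignedPair("a", "b", "ACDE", "ACDE"))
        assert corr.pairs == [(i, i) for i in range(1, 5)]

    def test_hand_read_gapped_mapping(self):
        corr = correspondence(AlignedPair("a", "b", "AB-D", "ABCD"))
        assert map_residue(corr, 3, "a") == 4  # D sits at partner position 4
        assert map_residue(corr, 3, "b") is None  # C aligned to a gap

    def test_round_trip_on_matched_positions(self):
        corr = correspondence(AlignedPair("a", "b", "AC-EF", "ACD-F"))
        for pa, pb in corr.pairs:
            assert map_residue(corr, pa, "a") == pb
            assert map_residue(corr, pb, "b") == pa

    def test_monotonicity_holds_for_aligner_output(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9))
            corr = correspondence(global_align(a, b))  # validates monotonic
            assert len(corr.pairs) <= min(12, 9)

    def test_out_of_range_errors(self):
        corr = correspondence(AlignedPair("a", "b", "ACDE", "ACDE"))
        with pytest.raises(IndexError):
            map_residue(corr, 5, "a")


class TestCallConserved:
    def test_recovers_protected_core_exactly(self):
        ancestral = random_protein(400, seed=2)
        protected = frozenset({7, 40, 200, 333})
        ortho = simulate_ortholog(
            ancestral,
            OrthologSpec(name="y", target_identity=0.25, protected=protected, seed=4),
        )
        pair = AlignedPair("h", "y", ortho.row_ancestral, ortho.row_ortholog)
        truth = set(ortho.conserved_positions)
        calls = call_conserved(range(1, 401), ancestral, {"y": pair})
        called = {c.human_pos for c in calls if c.conserved}
        assert called == truth  # 100% precision and recall, noiseless
        assert protected <= called

    def test_position_aligned_to_gap_is_not_conserved(self):
        pair = AlignedPair("h", "y", "ACDE", "A-DE")
        calls = call_conserved([2], "ACDE", {"y": pair})
        assert calls[0].status == {"y": "gap"}
        assert not calls[0].conserved

    def test_conserved_in_at_least_one_ortholog(self):
        p1 = AlignedPair("h", "y1", "ACDE", "AFDE")
        p2 = AlignedPair("h", "y2", "ACDE", "ACFE")
        calls = call_conserved([2, 3], "ACDE", {"y1": p1, "y2": p2})
        by_pos = {c.human_pos: c for c in calls}
        assert by_pos[2].conserved  # identical in y2
        assert by_pos[3].conserved  # identical in y1

    def test_similarity_mode_accepts_positive_score_substitutions(self):
        # D->E scores positive in BLOSUM62, D->P negative
        pair = AlignedPair("h", "y", "ADP", "AEG")
        strict = call_conserved([2, 3], "ADP", {"y": pair})
        assert not any(c.conserved for c in strict)
        relaxed = call_conserved([2, 3], "ADP", {"y": pair}, mode="similar")
        by_pos = {c.human_pos: c.conserved for c in relaxed}
        assert by_pos[2] and not by_pos[3]

    def test_mismatched_human_sequence_errors(self):
        pair = AlignedPair("h", "y", "ACDE", "ACDE")
        with pytest.raises(ValueError, match="human sequence"):
            call_conserved([1], "ACDF", {"y": pair})


class TestHRBlock:
    def test_identical_rows_conserve_every_column(self):
        assert hr_block_alignment(["ACDE"] * 4) == [1, 2, 3, 4]

    def test_one_divergent_row_conserves_nothing(self):
        assert hr_block_alignment(["AAAA", "AAAA", "AAAA", "CDEF"]) == []

    def test_planted_shared_columns(self):
        rows = ["AXCXE", "AYCYE", "AZCZE", "AWCWE"]
        assert hr_block_alignment(rows) == [1, 3, 5]

    def test_ragged_block_errors(self):
        with pytest.raises(ValueError):
            hr_block_alignment(["ACDE", "ACD", "ACDE", "ACDE"])
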