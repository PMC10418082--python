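"""Smith-Waterman kernel, annotation assignment and 3'-end classification."""

import random

import pytest

from trnacharge.align import (
    ALIGN_SCHEME,
    REALIGN_SCHEME,
    ScoringScheme,
    align_read,
    annotate,
    classify_3prime_end,
    smith_waterman,
    sw_score,
)
from trnacharge.preprocess import reverse_complement
from trnacharge.reference import ReferenceSet, TranscriptRecord

from conftest import random_seq, sw_oracle


class TestKernelExamples:
    def test_identity_scores_full_length(self):
        seq = "ACGTACGTAC"
        hit = smith_waterman(seq, seq, ALIGN_SCHEME)
        assert hit.score == 10
        assert hit.ops == "=" * 10
        assert hit.query_interval == (0, 10) and hit.ref_interval == (0, 10)

    def test_single_substitution_read_through(self):
        # reading through the mismatch (9*1 - 3 = 6) beats two split segments
        q = "AAAAACAAAA"
        r = "AAAAAGAAAA"
        assert sw_score(q, r, ALIGN_SCHEME) == 6

    def test_masked_position_neutralizes_mismatch(self):
        q = "AAAAACAAAA"
        r = "AAAAANAAAA"
        assert sw_score(q, r, ALIGN_SCHEME) == 9

    def test_n_column_scores_zero_for_any_base(self):
        for base in "ACGT":
            assert sw_score(base * 5, "AANAA", ALIGN_SCHEME) <= 5
        assert sw_score("AAAAA", "AANAA", ALIGN_SCHEME) == 4

    def test_gap_cost_convention(self):
        # deleting 2 ref bases: 20 matches - (6 + 3) = 11
        r = "ACGTACGTAC" + "GG" + "TTGCATGCAT"
        q = "ACGTACGTAC" + "TTGCATGCAT"
        assert sw_score(q, r, ALIGN_SCHEME) == 11

    def test_score_recomputable_from_ops(self):
        rng = random.Random(1)
        for _ in range(50):
            q = random_seq(rng, rng.randint(5, 30))
            r = random_seq(rng, rng.randint(5, 30), "ACGTN")
            hit = smith_waterman(q, r, ALIGN_SCHEME)
            if hit.ops:
                assert hit.rescore(q, r, ALIGN_SCHEME) == hit.score


class TestOracleEquivalence:
    @pytest.mark.parametrize("scheme", [ALIGN_SCHEME, REALIGN_SCHEME], ids=["align", "realign"])
    @pytest.mark.parametrize("masked", [False, True], ids=["plain", "masked"])
    def test_matches_exhaustive_dp(self, scheme, masked):
        rng = random.Random(42 if masked else 24)
        alphabet = "ACGTN" if masked else "ACGT"
        for _ in range(120):
            q = random_seq(rng, rng.randint(1, 30))
            r = random_seq(rng, rng.randint(1, 30), alphabet)
            expected = sw_oracle(q, r, scheme)
            assert sw_score(q, r, scheme) == expected
            assert smith_waterman(q, r, scheme).score == expected


class TestKernelProperties:
    def test_self_alignment_is_match_times_length(self):
        rng = random.Random(7)
        for _ in range(20):
            s = random_seq(rng, rng.randint(5, 60))
            assert sw_score(s, s, ALIGN_SCHEME) == len(s)

    def test_masking_bound(self):
        """|masked - unmasked| <= masked positions covered * max(|match|,|mismatch|)."""
        rng = random.Random(13)
        for _ in range(50):
            r = random_seq(rng, 40)
            q = r[5:35]
            n_mask = rng.randint(0, 6)
            positions = sorted(rng.sample(range(40), n_mask))
            masked = "".join("N" if i in positions else b for i, b in enumerate(r))
            s_plain = sw_score(q, r, ALIGN_SCHEME)
            s_masked = sw_score(q, masked, ALIGN_SCHEME)
            bound = n_mask * max(abs(ALIGN_SCHEME.match), abs(ALIGN_SCHEME.mismatch))
            assert abs(s_masked - s_plain) <= bound


class TestAlignRead:
    def test_error_free_read_hits_its_transcript(self, toy_reference):
        rec = toy_reference["tRNA-Ala-AGC-1-1"]
        hits = align_read(rec.sequence[-40:], toy_reference)
        assert hits and hits[0].transcript_id == "tRNA-Ala-AGC-1-1"

    def test_family_tie_reports_both_members(self, toy_reference):
        # the two Lys-TTT members differ only at position -4; a read from the
        # shared region scores identically against both
        shared = toy_reference["tRNA-Lys-TTT-1-1"].sequence[:40]
        hits = align_read(shared, toy_reference)
        assert {h.transcript_id for h in hits} == {"tRNA-Lys-TTT-1-1", "tRNA-Lys-TTT-1-2"}
        assert hits[0].score == hits[1].score

    def test_random_read_unmapped(self, toy_reference):
        rng = random.Random(99)
        for _ in range(5):
            q = random_seq(rng, 30)
            best = max(
                sw_oracle(q, rec.sequence, ALIGN_SCHEME) for rec in toy_reference
            )
            hits = align_read(q, toy_reference, min_score=20)
            if best < 20:
                assert hits == []
            else:
                assert hits

    def test_reverse_complement_unmapped(self, toy_reference):
        read = toy_reference["tRNA-His-GTG-1-1"].sequence[-40:]
        assert align_read(reverse_complement(read), toy_reference, min_score=25) == []


class TestAnnotate:
    def _ref_with_family(self):
        base = "GCCCGGATAGCTCAGTCGGTAGAGCATCAGACTTTAATCTGAGGGTCCAGGGTTCAAGTCCCTG"
        return ReferenceSet(
            [
                TranscriptRecord(id="tRNA-Lys-TTT-1-1", sequence=base + "TTCGAACGCCA",
                                 amino_acid="Lys", anticodon="TTT"),
                TranscriptRecord(id="tRNA-Lys-TTT-1-2", sequence=base + "GGCATTAGCCA",
                                 amino_acid="Lys", anticodon="TTT"),
                TranscriptRecord(id="tRNA-Lys-CTT-2-1", sequence=base + "ATACGGTTCCA",
                                 amino_acid="Lys", anticodon="CTT"),
            ]
        )

    def test_single_hit_all_unique(self, toy_reference):
        rec = toy_reference["tRNA-His-GTG-1-1"]
        ann = annotate(align_read(rec.sequence[-40:], toy_reference), toy_reference, seq=rec.sequence[-40:])
        assert ann.unique_transcript and ann.unique_anticodon and ann.unique_amino_acid

    def test_two_tied_same_anticodon(self):
        ref = self._ref_with_family()
        shared = ref["tRNA-Lys-TTT-1-1"].sequence[:40]
        ann = annotate(align_read(shared, ref), ref, seq=shared)
        assert not ann.unique_transcript
        # shared region ties all three family members -> anticodon not unique,
        # amino acid unique
        assert not ann.unique_anticodon
        assert ann.unique_amino_acid

    def test_uniqueness_flags_nested(self, toy_reference):
        rng = random.Random(5)
        for rec in toy_reference:
            read = rec.sequence[-35:]
            hits = align_read(read, toy_reference)
            ann = annotate(hits, toy_reference, seq=read)
            if ann.unique_transcript:
                assert ann.unique_anticodon
            if ann.unique_anticodon:
                assert ann.unique_amino_acid


class TestEndClassification:
    def _classify(self, read, toy_reference, tid="tRNA-His-GTG-1-1"):
        hits = align_read(read, toy_reference)
        assert hits and hits[0].transcript_id == tid
        return classify_3prime_end(hits[0], toy_reference[tid], read)

    def test_full_cca_end(self, toy_reference):
        read = toy_reference["tRNA-His-GTG-1-1"].sequence[-40:]
        assert read.endswith("CCA")
        assert self._classify(read, toy_reference) == "CCA"

    def test_cc_end_one_base_short(self, toy_reference):
        read = toy_reference["tRNA-His-GTG-1-1"].sequence[-40:-1]
        assert read.endswith("CC")
        assert self._classify(read, toy_reference) == "CC"

    def test_truncated_two_bases_is_other(self, toy_reference):
        read = toy_reference["tRNA-His-GTG-1-1"].sequence[-40:-2]
        assert self._classify(read, toy_reference) == "other"

    def test_terminal_mismatch_is_other(self, toy_reference):
        read = toy_reference["tRNA-His-GTG-1-1"].sequence[-40:-1] + "G"
        hits = align_read(read, toy_reference)
        cls = classify_3prime_end(hits[0], toy_reference[hits[0].transcript_id], read)
        assert cls == "other"
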