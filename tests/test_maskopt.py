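"""Mask construction, donation, iteration and grid search."""

import random

import numpy as np
import pandas as pd
import pytest

from trnacharge.align import align_and_annotate
from trnacharge.maskopt import (
    MaskingParams,
    build_mask,
    donate_masks,
    evaluate_mask,
    grid_search,
    iterate_masking,
    mismatch_frequencies,
    select_mask_positions,
)
from trnacharge.preprocess import preprocess_sample
from trnacharge.reference import MaskSet, ReferenceSet, TranscriptRecord, apply_mask
from trnacharge.simulate import (
    DEFAULT_ADAPTERS,
    Hotspot,
    simulate_reads,
    simulate_reference,
    uniform_truth,
)

from conftest import random_seq


def freq_frame(rows):
    return pd.DataFrame(rows, columns=["transcript", "position", "obs", "freq"])


@pytest.fixture(scope="module")
def hotspot_family():
    """Two-anticodon sister transcripts separable at two positions: a
    hypermutated (modified) position and an unmodified diagnostic position.

    When the modification misincorporates toward the sister's base, the read
    carries one mismatch against either transcript — a score tie and a
    multi-anticodon assignment.  Masking the modified position removes that
    penalty asymmetrically (the unmodified diagnostic position still
    separates the pair), so masking strictly reduces multi-anticodon reads.
    """
    rng = random.Random(17)
    body = random_seq(rng, 69)
    seq_a = list(body)
    seq_b = list(body)
    diag, hot_pos = 50, 40
    seq_a[diag], seq_b[diag] = "A", "G"
    seq_a[hot_pos], seq_b[hot_pos] = "A", "C"
    ref = ReferenceSet(
        [
            TranscriptRecord(id="tRNA-Lys-TTT-1-1", sequence="".join(seq_a) + "CCA",
                             amino_acid="Lys", anticodon="TTT"),
            TranscriptRecord(id="tRNA-Lys-CTT-2-1", sequence="".join(seq_b) + "CCA",
                             amino_acid="Lys", anticodon="CTT"),
        ]
    )
    truth = uniform_truth(ref, charge=0.7, seed=17, seq_error=0.001)
    truth.hotspots = {
        tid: [Hotspot(position=hot_pos, mismatch_prob=0.55)] for tid in ref.ids()
    }
    reads, _ = simulate_reads(ref, truth, 1600)
    processed, _ = preprocess_sample(reads, DEFAULT_ADAPTERS, "s")
    return ref, processed, hot_pos


class TestFrequencies:
    def _annotations(self, ref, processed):
        anns, _ = align_and_annotate(processed, ref)
        return anns

    def test_filters_applied(self, hotspot_family):
        ref, processed, hot_pos = hotspot_family
        anns = self._annotations(ref, processed)
        freqs = mismatch_frequencies(anns, ref, unique_anno=True)
        assert not freqs.empty
        assert (freqs.obs >= 100).all()
        # hotspot position present with elevated frequency
        hot = freqs[freqs.position == hot_pos]
        assert not hot.empty and (hot.freq > 0.3).any()

    def test_low_observation_transcript_absent(self):
        # 150 observations fail the >=200 transcript filter; 300 pass, but
        # positions covered by fewer than 100 reads stay absent
        ref, _ = simulate_reference(n_families=1, members_per_family=1, seed=2)
        truth = uniform_truth(ref, charge=0.8, seed=2)
        for n, expect_empty in ((150, True), (300, False)):
            reads, _ = simulate_reads(ref, truth, n)
            processed, _ = preprocess_sample(reads, DEFAULT_ADAPTERS, "s")
            anns, _ = align_and_annotate(processed, ref)
            freqs = mismatch_frequencies(anns, ref, unique_anno=True)
            assert freqs.empty == expect_empty
            if not freqs.empty:
                assert (freqs.obs >= 100).all()

    def test_simple_frequency_arithmetic(self):
        freqs = freq_frame([("t", 30, 200, 2 / 200)])
        assert freqs.freq.iloc[0] == pytest.approx(0.01)


class TestSelect:
    def _ref(self):
        return ReferenceSet([TranscriptRecord(id="t", sequence="ACGT" * 18 + "CCA")])

    def test_unattainable_threshold_empty(self):
        freqs = freq_frame([("t", 10, 500, 0.5)])
        assert select_mask_positions(freqs, self._ref(), min_mut_freq=1.1).n_masked() == 0

    def test_inclusive_boundary(self):
        ref = self._ref()
        freqs = freq_frame([("t", 10, 500, 0.20), ("t", 11, 500, 0.0999)])
        mask = select_mask_positions(freqs, ref, min_mut_freq=0.10)
        assert mask == MaskSet({"t": {10}})

    def test_cca_tail_never_masked(self):
        ref = self._ref()
        L = len(ref["t"].sequence)
        freqs = freq_frame([("t", L - 1, 500, 0.9), ("t", L - 3, 500, 0.9), ("t", 5, 500, 0.9)])
        mask = select_mask_positions(freqs, ref, min_mut_freq=0.1)
        assert mask == MaskSet({"t": {5}})


class TestDonation:
    def _pair(self, same=True):
        rng = random.Random(8)
        body = random_seq(rng, 70)
        other = list(body)
        if not same:
            other[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[30]]
        return ReferenceSet(
            [
                TranscriptRecord(id="donor", sequence=body + "CCA"),
                TranscriptRecord(id="acceptor", sequence="".join(other) + "CCA"),
            ]
        )

    def test_identical_pair_copies_mask(self):
        ref = self._pair(same=True)
        mask = MaskSet({"donor": {30}})
        out = donate_masks(mask, ref, freq_frame([]), frac_max_score=1.0)
        assert out["acceptor"] == {30}

    def test_nucleotide_mismatch_blocks_copy(self):
        ref = self._pair(same=False)
        mask = MaskSet({"donor": {30}})
        out = donate_masks(mask, ref, freq_frame([]), frac_max_score=0.9)
        assert "acceptor" not in out or 30 not in out["acceptor"]

    def test_observed_acceptor_position_blocks_copy(self):
        ref = self._pair(same=True)
        mask = MaskSet({"donor": {30}})
        freqs = freq_frame([("acceptor", 30, 150, 0.0)])
        out = donate_masks(mask, ref, freqs, frac_max_score=1.0)
        assert "acceptor" not in out or 30 not in out["acceptor"]

    def test_dissimilar_pair_no_donation(self):
        rng = random.Random(12)
        ref = ReferenceSet(
            [
                TranscriptRecord(id="donor", sequence=random_seq(rng, 70) + "CCA"),
                TranscriptRecord(id="acceptor", sequence=random_seq(rng, 70) + "CCA"),
            ]
        )
        out = donate_masks(MaskSet({"donor": {30}}), ref, freq_frame([]), frac_max_score=0.9)
        assert "acceptor" not in out


class TestIteration:
    def test_single_iteration_equals_single_pass(self, hotspot_family):
        ref, processed, _ = hotspot_family
        params = MaskingParams(unique_anno=True, min_mut_freq=0.2, frac_max_score=0.95, iteration=1)
        mask = iterate_masking(processed, ref, params)
        anns, _ = align_and_annotate(processed, ref)
        assert mask == build_mask(anns, ref, params)

    def test_error_free_reads_yield_empty_mask(self):
        ref, _ = simulate_reference(n_families=2, members_per_family=1, seed=5)
        truth = uniform_truth(ref, charge=0.8, seed=5, seq_error=0.0)
        reads, _ = simulate_reads(ref, truth, 900)
        processed, _ = preprocess_sample(reads, DEFAULT_ADAPTERS, "s")
        params = MaskingParams(min_mut_freq=0.05, iteration=1)
        assert iterate_masking(processed, ref, params).n_masked() == 0

    def test_planted_hotspot_masked(self, hotspot_family):
        ref, processed, hot_pos = hotspot_family
        params = MaskingParams(unique_anno=False, min_mut_freq=0.2, frac_max_score=0.9, iteration=2)
        log = []
        mask = iterate_masking(processed, ref, params, log=log)
        assert any(hot_pos in mask.get(tid, set()) for tid in ref.ids())
        assert len(log) == 2

    def test_iteration_stability(self, hotspot_family):
        ref, processed, _ = hotspot_family
        params = MaskingParams(unique_anno=False, min_mut_freq=0.2, frac_max_score=0.9, iteration=3)
        log = []
        iterate_masking(processed, ref, params, log=log)
        assert abs(log[-1] - log[-2]) <= max(1, 0.05 * max(log[-1], 1))


class TestGridSearch:
    def test_single_combination_returned(self, hotspot_family):
        ref, processed, _ = hotspot_family
        params = MaskingParams(unique_anno=False, min_mut_freq=0.3, frac_max_score=0.9, iteration=1)
        best, results = grid_search(processed, ref, [params])
        assert best.params == params and len(results) == 1

    def test_masking_reduces_multi_anticodon(self, hotspot_family):
        """Optimal mask strictly reduces multi-anticodon assignment without
        costing more than 1 pp of mapped reads."""
        ref, processed, _ = hotspot_family
        grid = [
            MaskingParams(u, f, 0.9, it)
            for u in (False, True)
            for f in (0.2, 0.4)
            for it in (1, 2)
        ]
        baseline_multi, baseline_mapped = evaluate_mask(processed, ref, MaskSet())
        best, _ = grid_search(processed, ref, grid)
        assert best.pct_multi_anticodon < baseline_multi
        assert best.pct_mapped >= baseline_mapped - 1.0

    def test_tie_prefers_smaller_mask(self, hotspot_family):
        ref, processed, _ = hotspot_family
        loose = MaskingParams(unique_anno=False, min_mut_freq=0.2, frac_max_score=0.9, iteration=1)
        none_ = MaskingParams(unique_anno=False, min_mut_freq=1.0, frac_max_score=0.9, iteration=1)
        best, results = grid_search(processed, ref, [loose, none_])
        objectives = [r.pct_multi_anticodon for r in results]
        if objectives[0] == objectives[1]:
            assert best.mask_size == min(r.mask_size for r in results)

    def test_mask_preserves_reference_length(self, hotspot_family):
        ref, processed, _ = hotspot_family
        params = MaskingParams(unique_anno=False, min_mut_freq=0.2, frac_max_score=0.9, iteration=1)
        mask = iterate_masking(processed, ref, params)
        masked = apply_mask(ref, mask)
        for rec, orig in zip(masked, ref):
            assert len(rec.sequence) == len(orig.sequence)
            diffs = {i for i, (a, b) in enumerate(zip(rec.sequence, orig.sequence)) if a != b}
            assert diffs == mask.get(rec.id, set())
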