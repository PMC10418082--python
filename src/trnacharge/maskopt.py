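"""Iterative reference-mask construction and grid-search tuning.

Modification-induced mismatches make reads from one transcript align equally
well (or better) to a similar family member, inflating multi-transcript and
multi-anticodon assignments.  Masking high-mismatch reference positions to N
(scored neutrally) removes that penalty.  The mask is built from position-wise
mismatch frequencies under four tuning parameters:

``unique_anno``
    Count only reads with a unique transcript annotation when computing
    frequencies.
``min_mut_freq``
    Minimum (inclusive) mismatch frequency that triggers masking.
``frac_max_score``
    Minimum (inclusive) fraction of the pairwise maximum alignment score at
    which an abundant transcript donates its masked positions to a highly
    similar, less abundant one — requiring the same nucleotide at the mapped
    pair and fewer than 100 observations at the acceptor position.
``iteration``
    Number of mask/re-align iterations; re-masking changes annotations and
    therefore frequencies, and iterating stabilises the mask.

Frequencies are filtered to transcripts with at least 200 (UMI-corrected)
observations and positions with at least 100; the 3'-terminal CCA positions
are never maskable, since charge classification requires terminal matches.
The grid search minimises the percentage of reads assigned to transcripts
with multiple anticodons (ties: smaller mask, then stable grid order) while
also reporting the mapped-read percentage to expose any specificity/
sensitivity trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trnacharge.align import (
    ALIGN_SCHEME,
    OP_DEL,
    OP_INS,
    ReadAnnotation,
    ScoringScheme,
    align_and_annotate,
    smith_waterman,
    sw_score,
)
from trnacharge.modprofile import realign_annotations, build_profiles
from trnacharge.reference import MaskSet, ReferenceSet, apply_mask

MIN_TRANSCRIPT_OBS = 200
MIN_POSITION_OBS = 100
ACCEPTOR_MAX_OBS = 100
CCA_TAIL = 3  # 3'-terminal positions that must stay unmasked


@dataclass(frozen=True)
class MaskingParams:
    unique_anno: bool = True
    min_mut_freq: float = 0.1
    frac_max_score: float = 0.9
    iteration: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.min_mut_freq <= 1:
            raise ValueError("min_mut_freq must be in (0, 1]")
        if not 0 < self.frac_max_score <= 1:
            raise ValueError("frac_max_score must be in (0, 1]")
        if self.iteration < 1:
            raise ValueError("iteration must be a positive count")


def default_grid() -> list[MaskingParams]:
    """Bracketing grid over all four tuning parameters."""
    return [
        MaskingParams(u, f, s, it)
        for u, f, s, it in product(
            (True, False), (0.05, 0.10, 0.15, 0.20), (0.85, 0.90, 0.95, 1.00), (1, 2, 3)
        )
    ]


def mismatch_frequencies(
    annotations: Sequence[ReadAnnotation],
    ref: ReferenceSet,
    unique_anno: bool = True,
    min_transcript_obs: int = MIN_TRANSCRIPT_OBS,
    min_position_obs: int = MIN_POSITION_OBS,
) -> pd.DataFrame:
    """Position-wise mismatch frequencies from unmasked realignments.

    Returns a frame (transcript, position, obs, freq) with the transcript- and
    position-level observation filters applied; entries failing a filter are
    absent, not zero-filled.  With ``unique_anno`` false, reads with multiple
    tied annotations contribute to each of their kept transcripts.
    """
    if unique_anno:
        pool = [a for a in annotations if a.unique_transcript]
        events = realign_annotations(pool, ref)
    else:
        events = realign_annotations(
            [a for a in annotations if a.unique_transcript], ref
        )
        # multi-annotation reads: realign against each kept tied transcript
        from trnacharge.modprofile import extract_events, realign_unmasked

        seen: set[tuple] = set()
        for ann in annotations:
            if ann.unique_transcript:
                continue
            for hit in ann.hits_kept:
                key = (ann.sample_id, hit.transcript_id, ann.seq, ann.umi)
                if key in seen:
                    continue
                seen.add(key)
                rehit = realign_unmasked(ann.seq, ref[hit.transcript_id].sequence)
                if rehit.ref_interval[1] - rehit.ref_interval[0] < 10:
                    continue
                events.append(extract_events(rehit, hit.transcript_id))
    profiles = build_profiles(events, ref)
    if profiles.empty:
        return pd.DataFrame(columns=["transcript", "position", "obs", "freq"])
    per_transcript = {ev.transcript_id: 0 for ev in events}
    for ev in events:
        per_transcript[ev.transcript_id] += 1
    out = profiles.rename(columns={"coverage": "obs", "mismatch_frac": "freq"})[
        ["transcript", "position", "obs", "freq"]
    ].copy()
    out["transcript_obs"] = out.transcript.map(per_transcript)
    out = out[(out.transcript_obs >= min_transcript_obs) & (out.obs >= min_position_obs)]
    return out.drop(columns="transcript_obs").reset_index(drop=True)


def select_mask_positions(
    freqs: pd.DataFrame, ref: ReferenceSet, min_mut_freq: float
) -> MaskSet:
    """Mask positions whose mismatch frequency is >= ``min_mut_freq``.

    The last ``CCA_TAIL`` positions of each transcript are never masked.
    """
    mask = MaskSet()
    if freqs.empty:
        return mask
    hot = freqs[freqs.freq >= min_mut_freq]
    for tid, grp in hot.groupby("transcript"):
        limit = len(ref[tid].sequence) - CCA_TAIL
        positions = {int(p) for p in grp.position if p < limit}
        if positions:
            mask[tid] = positions
    return mask


def _map_positions(donor_seq: str, acceptor_seq: str, scheme: ScoringScheme) -> dict[int, int]:
    """Map donor reference positions to acceptor positions through the pairwise
    alignment (diagonal columns only)."""
    hit = smith_waterman(donor_seq, acceptor_seq, scheme)
    mapping: dict[int, int] = {}
    qi, ri = hit.query_interval[0], hit.ref_interval[0]
    for op in hit.ops:
        if op in ("=", "X"):
            mapping[qi] = ri
            qi += 1
            ri += 1
        elif op == OP_INS:
            qi += 1
        elif op == OP_DEL:
            ri += 1
    return mapping


def donate_masks(
    mask: MaskSet,
    ref: ReferenceSet,
    freqs: pd.DataFrame,
    frac_max_score: float,
    scheme: ScoringScheme = ALIGN_SCHEME,
) -> MaskSet:
    """Expand a mask from abundant transcripts to highly similar ones.

    For each ordered (donor, acceptor) pair with pairwise score >=
    ``frac_max_score`` x min(self-score(donor), self-score(acceptor)), each
    donor masked position maps through the pairwise alignment and is copied
    iff the reference nucleotides agree at the mapped pair and the acceptor
    position has fewer than 100 observations.
    """
    out = mask.copy()
    donors = [tid for tid in mask if mask[tid]]
    if not donors:
        return out
    obs_lookup = {}
    if not freqs.empty:
        obs_lookup = {
            (t, int(p)): int(o) for t, p, o in zip(freqs.transcript, freqs.position, freqs.obs)
        }
    self_scores = {rec.id: sw_score(rec.sequence, rec.sequence, scheme) for rec in ref}
    for donor_id in donors:
        donor = ref[donor_id]
        for acceptor in ref:
            if acceptor.id == donor_id:
                continue
            pair_score = sw_score(donor.sequence, acceptor.sequence, scheme)
            if pair_score < frac_max_score * min(self_scores[donor_id], self_scores[acceptor.id]):
                continue
            mapping = _map_positions(donor.sequence, acceptor.sequence, scheme)
            limit = len(acceptor.sequence) - CCA_TAIL
            for pos in mask[donor_id]:
                tgt = mapping.get(pos)
                if tgt is None or tgt >= limit:
                    continue
                if donor.sequence[pos] != acceptor.sequence[tgt]:
                    continue
                if obs_lookup.get((acceptor.id, tgt), 0) >= ACCEPTOR_MAX_OBS:
                    continue
                out.setdefault(acceptor.id, set()).add(tgt)
    return out


def build_mask(
    annotations: Sequence[ReadAnnotation],
    ref: ReferenceSet,
    params: MaskingParams,
) -> MaskSet:
    """One masking pass: frequencies -> select -> donate."""
    freqs = mismatch_frequencies(annotations, ref, unique_anno=params.unique_anno)
    mask = select_mask_positions(freqs, ref, params.min_mut_freq)
    return donate_masks(mask, ref, freqs, params.frac_max_score)


def iterate_masking(
    reads: Sequence,
    ref: ReferenceSet,
    params: MaskingParams,
    scheme: ScoringScheme = ALIGN_SCHEME,
    min_score: int = 20,
    log: list | None = None,
) -> MaskSet:
    """Iteratively align -> profile -> mask, ``params.iteration`` times.

    Each iteration re-aligns the reads against the current masked reference
    (starting unmasked) and rebuilds the mask from the fresh annotations;
    per-iteration mask sizes are appended to ``log`` when given.
    """
    mask = MaskSet()
    for _ in range(params.iteration):
        masked_ref = apply_mask(ref, mask)
        annotations, _ = align_and_annotate(reads, masked_ref, scheme, min_score)
        mask = build_mask(annotations, ref, params)
        if log is not None:
            log.append(mask.n_masked())
    return mask


@dataclass
class GridResult:
    params: MaskingParams
    mask: MaskSet
    pct_multi_anticodon: float
    pct_mapped: float

    @property
    def mask_size(self) -> int:
        return self.mask.n_masked()


def evaluate_mask(
    reads: Sequence,
    ref: ReferenceSet,
    mask: MaskSet,
    scheme: ScoringScheme = ALIGN_SCHEME,
    min_score: int = 20,
) -> tuple[float, float]:
    """(pct_multi_anticodon among mapped reads, pct_mapped of all reads)."""
    masked_ref = apply_mask(ref, mask)
    annotations, stats = align_and_annotate(reads, masked_ref, scheme, min_score)
    n_mapped = stats["mapped"]
    if n_mapped == 0:
        return float("nan"), 0.0
    n_multi = sum(1 for a in annotations if not a.unique_anticodon)
    return 100.0 * n_multi / n_mapped, 100.0 * n_mapped / stats["input"]


def grid_search(
    reads: Sequence,
    ref: ReferenceSet,
    grid: Sequence[MaskingParams] | None = None,
    scheme: ScoringScheme = ALIGN_SCHEME,
    min_score: int = 20,
) -> tuple[GridResult, list[GridResult]]:
    """Evaluate every parameter combination; return (best, all).

    Best = minimum pct_multi_anticodon; ties break to the smaller mask, then
    to stable grid order.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must be nonempty")
    results = []
    for params in grid:
        mask = iterate_masking(reads, ref, params, scheme, min_score)
        pct_multi, pct_mapped = evaluate_mask(reads, ref, mask, scheme, min_score)
        results.append(GridResult(params, mask, pct_multi, pct_mapped))
    best = min(
        enumerate(results),
        key=lambda kv: (kv[1].pct_multi_anticodon, kv[1].mask_size, kv[0]),
    )[1]
    return best, results


def grid_report(results: Iterable[GridResult]) -> pd.DataFrame:
    rows = [
        {
            "unique_anno": r.params.unique_anno,
            "min_mut_freq": r.params.min_mut_freq,
            "frac_max_score": r.params.frac_max_score,
            "iteration": r.params.iteration,
            "pct_multi_anticodon": r.pct_multi_anticodon,
            "pct_mapped": r.pct_mapped,
            "mask_size": r.mask_size,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
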