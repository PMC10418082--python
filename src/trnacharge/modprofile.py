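"""Per-position misincorporation and RT-stop profiles.

Reverse transcriptases stumble on modified nucleotides, leaving mismatches,
gaps and premature terminations (RT stops) that act as sequence-readable
modification signatures.  Reads with a unique transcript annotation are
re-aligned to their *unmasked* transcript with a softer scoring scheme
(match +1, mismatch -2, gap open -3, gap extend -2) so modified positions
produce mismatch columns instead of clipped alignments; the masked primary
alignment is deliberately not reused for this purpose.

cDNA synthesis starts at the tRNA 3' end, so RT falloff truncates the
transcript-5' side of reads: coverage is non-increasing moving 3'->5', and
the RT-stop percentage at position p is the percentage of (UMI-corrected)
molecules whose alignment's 5'-most reference index is exactly p+1, relative
to the maximum 3'-side coverage.

Conventions: a mismatch is attributed to the reference index of its column; a
deletion to the reference index of its 5'-most deleted base; an insertion to
the reference index immediately 3' of the inserted bases.  All counts are
UMI-corrected (identical sequence+UMI counts once).  Realignments covering
fewer than ``min_span`` reference positions are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trnacharge.align import (
    OP_DEL,
    OP_INS,
    OP_MATCH,
    OP_MISMATCH,
    REALIGN_SCHEME,
    AlignmentHit,
    ReadAnnotation,
    ScoringScheme,
    smith_waterman,
)
from trnacharge.reference import ReferenceSet


def realign_unmasked(
    seq: str,
    transcript_seq: str,
    scheme: ScoringScheme = REALIGN_SCHEME,
) -> AlignmentHit:
    """Re-align a read to its unmasked annotated transcript for profiling."""
    return smith_waterman(seq, transcript_seq, scheme)


@dataclass
class RealignEvents:
    """Per-read reference-coordinate events extracted from one realignment."""

    transcript_id: str
    ref_start: int  # 5'-most aligned reference index
    ref_end: int  # half-open
    mismatch_positions: tuple[int, ...]
    gap_positions: tuple[int, ...]


def extract_events(hit: AlignmentHit, transcript_id: str) -> RealignEvents:
    """Walk the alignment ops and attribute mismatches and gaps to reference
    positions under the module's conventions."""
    ri = hit.ref_interval[0]
    mismatches: list[int] = []
    gaps: list[int] = []
    ops = hit.ops
    k = 0
    while k < len(ops):
        op = ops[k]
        if op == OP_MATCH:
            ri += 1
            k += 1
        elif op == OP_MISMATCH:
            mismatches.append(ri)
            ri += 1
            k += 1
        elif op == OP_DEL:
            gaps.append(ri)  # 5'-most deleted base
            while k < len(ops) and ops[k] == OP_DEL:
                ri += 1
                k += 1
        else:  # insertion: ref index immediately 3' of the inserted bases
            gaps.append(ri)
            while k < len(ops) and ops[k] == OP_INS:
                k += 1
    return RealignEvents(
        transcript_id=transcript_id,
        ref_start=hit.ref_interval[0],
        ref_end=hit.ref_interval[1],
        mismatch_positions=tuple(mismatches),
        gap_positions=tuple(gaps),
    )


def realign_annotations(
    annotations: Iterable[ReadAnnotation],
    ref: ReferenceSet,
    scheme: ScoringScheme = REALIGN_SCHEME,
    min_span: int = 10,
    umi_corrected: bool = True,
) -> list[RealignEvents]:
    """Realign unique-transcript reads to their unmasked transcripts.

    With ``umi_corrected`` (default) duplicate (sample, transcript, sequence,
    UMI) reads are realigned once and counted once.
    """
    events = []
    seen: set[tuple] = set()
    for ann in annotations:
        if not ann.unique_transcript:
            continue
        tid = ann.best_hit.transcript_id
        if umi_corrected:
            key = (ann.sample_id, tid, ann.seq, ann.umi)
            if key in seen:
                continue
            seen.add(key)
        hit = realign_unmasked(ann.seq, ref[tid].sequence, scheme)
        if hit.ref_interval[1] - hit.ref_interval[0] < min_span:
            continue
        events.append(extract_events(hit, tid))
    return events


def build_profiles(
    realignments: Sequence[RealignEvents],
    ref: ReferenceSet,
) -> pd.DataFrame:
    """Aggregate realignment events into per-position profiles.

    Returns a frame with columns transcript, position (0-based), coverage,
    mismatch_frac, gap_frac, rt_stop_pct.  Positions with zero coverage have
    NaN fractions (flagged, not zero-filled).
    """
    rows = []
    by_tid: dict[str, list[RealignEvents]] = {}
    for ev in realignments:
        by_tid.setdefault(ev.transcript_id, []).append(ev)
    for tid in sorted(by_tid):
        evs = by_tid[tid]
        length = len(ref[tid].sequence)
        coverage = np.zeros(length, dtype=np.int64)
        mism = np.zeros(length, dtype=np.int64)
        gaps = np.zeros(length, dtype=np.int64)
        starts = np.zeros(length + 1, dtype=np.int64)  # alignments starting at p
        for ev in evs:
            coverage[ev.ref_start : ev.ref_end] += 1
            starts[ev.ref_start] += 1
            for p in ev.mismatch_positions:
                mism[p] += 1
            for p in ev.gap_positions:
                if p < length:
                    gaps[p] += 1
        max_cov = int(coverage.max())
        for p in range(length):
            cov = int(coverage[p])
            # molecules whose alignment terminates before reaching p: their
            # 5'-most index is exactly p+1
            rt_stop = 100.0 * starts[p + 1] / max_cov if max_cov else float("nan")
            rows.append(
                {
                    "transcript": tid,
                    "position": p,
                    "coverage": cov,
                    "mismatch_frac": mism[p] / cov if cov else float("nan"),
                    "gap_frac": gaps[p] / cov if cov else float("nan"),
                    "rt_stop_pct": rt_stop,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript", "position", "coverage", "mismatch_frac", "gap_frac", "rt_stop_pct"],
    )
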