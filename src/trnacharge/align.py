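"""Guaranteed-best local alignment of tRNA reads against a (masked) reference.

The reference is a few hundred sequences, so instead of heuristic seeding every
read is aligned against every transcript with an exhaustive affine-gap
Smith-Waterman (plus strand only), guaranteeing the best-scoring annotation.
Masked reference positions (``N``) score a configurable constant — 0 by
default — for any query base, so modification-induced misincorporations at
masked positions neither reward nor penalise an alignment.

Gap convention: a gap of length L costs ``gap_open + gap_extend * (L - 1)``;
the opening penalty covers the first gapped base.

Traceback ties are broken deterministically: diagonal (match/mismatch) is
preferred over deletion (gap in the read, reference base skipped) over
insertion (extra read base).  Among equal-scoring end cells the 3'-most
reference end, then the 3'-most query end, wins.  This makes misincorporation
profiles reproducible across runs and worker counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from trnacharge.reference import ReferenceSet, TranscriptRecord

# Base encoding shared by all kernels.  N (code 4) in the reference scores
# `n_score` against anything; N in the query is just a mismatch.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# op codes in AlignmentHit.ops
OP_MATCH = "="
OP_MISMATCH = "X"
OP_DEL = "D"  # reference base absent from the read
OP_INS = "I"  # read base absent from the reference


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Integer local-alignment scoring parameters.

    ``gap_open``/``gap_extend`` are penalties (non-negative); a length-L gap
    costs ``gap_open + gap_extend * (L - 1)``.
    """

    match: int = 1
    mismatch: int = -3
    n_score: int = 0
    gap_open: int = 6
    gap_extend: int = 3

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


#: Scheme used for the primary read-vs-masked-reference alignment.
ALIGN_SCHEME = ScoringScheme(match=1, mismatch=-3, n_score=0, gap_open=6, gap_extend=3)

#: Scheme used when re-aligning a read to its unmasked annotated transcript
#: for misincorporation profiling: match +1, mismatch -2, gap open -3,
#: gap extension -2 (as score contributions).
REALIGN_SCHEME = ScoringScheme(match=1, mismatch=-2, n_score=0, gap_open=3, gap_extend=2)


@dataclass
class AlignmentHit:
    """One optimal local alignment of a read against one transcript."""

    transcript_id: str
    score: int
    query_interval: tuple[int, int]  # 0-based half-open on the read
    ref_interval: tuple[int, int]  # 0-based half-open on the transcript
    ops: str  # one char per column: = X D I

    def rescore(self, query: str, ref_seq: str, scheme: ScoringScheme) -> int:
        """Recompute the score from the ops (consistency check)."""
        qi, ri = self.query_interval[0], self.ref_interval[0]
        score = 0
        k = 0
        ops = self.ops
        while k < len(ops):
            op = ops[k]
            if op in (OP_MATCH, OP_MISMATCH):
                if ref_seq[ri] == "N":
                    score += scheme.n_score
                elif query[qi] == ref_seq[ri]:
                    score += scheme.match
                else:
                    score += scheme.mismatch
                qi += 1
                ri += 1
                k += 1
            else:
                j = k
                while j < len(ops) and ops[j] == op:
                    j += 1
                length = j - k
                score -= scheme.gap_open + scheme.gap_extend * (length - 1)
                if op == OP_DEL:
                    ri += length
                else:
                    qi += length
                k = j
        return score


@dataclass
class ReadAnnotation:
    """Merged best-alignment annotation of one processed read.

    ``hits_kept`` holds up to three tied best-scoring transcripts; the
    uniqueness flags are nested (unique transcript implies unique anticodon
    implies unique amino acid) and, when more than three transcripts tie,
    are computed over *all* tied transcripts, not just the kept three.
    """

    read_id: str
    sample_id: str
    adapter_id: str
    umi: str
    seq: str
    hits_kept: list[AlignmentHit]
    unique_transcript: bool
    unique_anticodon: bool
    unique_amino_acid: bool
    end_class: str = "other"  # CCA | CC | other
    over_tied: bool = False
    anticodons: frozenset = frozenset()
    amino_acids: frozenset = frozenset()

    @property
    def best_hit(self) -> AlignmentHit:
        return self.hits_kept[0]


@njit(cache=True)
def _sw_score(q, r, match, mismatch, n_score, gap_open, gap_extend):
    """Best local score only; O(len(r)) memory."""
    NEG = -(10**9)
    n = r.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)  # holds row i-1, overwritten in place
    F = np.full(n + 1, NEG, dtype=np.int64)  # F[i][j] per column
    best = 0
    for i in range(1, q.shape[0] + 1):
        qc = q[i - 1]
        diag = 0  # H[i-1][j-1]
        e = NEG  # E[i][j-1]
        h_left = 0  # H[i][j-1]
        for j in range(1, n + 1):
            rc = r[j - 1]
            if rc == 4:
                sub = n_score
            elif qc == rc:
                sub = match
            else:
                sub = mismatch
            e = max(h_left - gap_open, e - gap_extend)
            f = max(H[j] - gap_open, F[j] - gap_extend)
            h = diag + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            F[j] = f
            h_left = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_full(q, r, match, mismatch, n_score, gap_open, gap_extend):
    """Full DP with affine-state matrices for traceback.

    Returns (H, E, F) with shape (m+1, n+1).
    """
    m, n = q.shape[0], r.shape[0]
    NEG = -10**9
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        qc = q[i - 1]
        for j in range(1, n + 1):
            rc = r[j - 1]
            if rc == 4:
                sub = n_score
            elif qc == rc:
                sub = match
            else:
                sub = mismatch
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


def smith_waterman(query: str, ref_seq: str, scheme: ScoringScheme = ALIGN_SCHEME) -> AlignmentHit:
    """Optimal local alignment of ``query`` against ``ref_seq``.

    Returns one optimal path; ties are broken deterministically (see module
    docstring).  Columns whose reference base is ``N`` contribute
    ``scheme.n_score`` regardless of the query base.
    """
    if not query or not ref_seq:
        raise ValueError("smith_waterman requires nonempty sequences")
    q, r = encode(query), encode(ref_seq)
    H, E, F = _sw_full(
        q, r, scheme.match, scheme.mismatch, scheme.n_score, scheme.gap_open, scheme.gap_extend
    )
    score = int(H.max())
    if score <= 0:
        return AlignmentHit("", 0, (0, 0), (0, 0), "")
    # end cell: highest score, then largest j (3'-most ref end), then largest i
    best_i, best_j = -1, -1
    m, n = len(query), len(ref_seq)
    for j in range(n, 0, -1):
        col = H[:, j]
        i = int(col.argmax())
        if col[i] == score:
            # among rows in this column prefer the largest i with the max
            rows = np.flatnonzero(col == score)
            best_i, best_j = int(rows[-1]), j
            break
    ops: list[str] = []
    i, j = best_i, best_j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            rc = r[j - 1]
            if rc == 4:
                sub = scheme.n_score
            elif q[i - 1] == rc:
                sub = scheme.match
            else:
                sub = scheme.mismatch
            if h == H[i - 1, j - 1] + sub:
                is_match = rc != 4 and q[i - 1] == rc
                ops.append(OP_MATCH if is_match else OP_MISMATCH)
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # deletion: gap in read, ref consumed
            ops.append(OP_DEL)
            if E[i, j] == H[i, j - 1] - scheme.gap_open:
                state = "H"
            j -= 1
        else:  # insertion: extra read base
            ops.append(OP_INS)
            if F[i, j] == H[i - 1, j] - scheme.gap_open:
                state = "H"
            i -= 1
    ops.reverse()
    hit = AlignmentHit(
        transcript_id="",
        score=score,
        query_interval=(i, best_i),
        ref_interval=(j, best_j),
        ops="".join(ops),
    )
    return hit


def sw_score(query: str, ref_seq: str, scheme: ScoringScheme = ALIGN_SCHEME) -> int:
    """Best local alignment score only (fast path)."""
    if not query or not ref_seq:
        raise ValueError("sw_score requires nonempty sequences")
    return int(
        _sw_score(
            encode(query),
            encode(ref_seq),
            scheme.match,
            scheme.mismatch,
            scheme.n_score,
            scheme.gap_open,
            scheme.gap_extend,
        )
    )


def align_read(
    seq: str,
    masked_ref: ReferenceSet,
    scheme: ScoringScheme = ALIGN_SCHEME,
    min_score: int = 20,
    max_hits: int = 3,
) -> list[AlignmentHit]:
    """Score ``seq`` against every transcript; return the tied best hits.

    All transcripts are scored (plus strand only); hits below ``min_score``
    are discarded and at most ``max_hits`` tied top-scoring transcripts are
    returned, in stable reference order.  An empty list means unmapped.
    """
    if len(masked_ref) == 0:
        raise ValueError("empty reference")
    q = encode(seq)
    scores = np.empty(len(masked_ref), dtype=np.int64)
    for k, rec in enumerate(masked_ref):
        scores[k] = _sw_score(
            q,
            encode(rec.sequence),
            scheme.match,
            scheme.mismatch,
            scheme.n_score,
            scheme.gap_open,
            scheme.gap_extend,
        )
    best = int(scores.max())
    if best < min_score:
        return []
    tied_idx = np.flatnonzero(scores == best)
    hits = []
    for k in tied_idx[:max_hits]:
        rec = masked_ref.records[int(k)]
        hit = smith_waterman(seq, rec.sequence, scheme)
        hit.transcript_id = rec.id
        hits.append(hit)
    # record the total tie count so annotate() can flag over-tied reads
    for h in hits:
        h.n_tied = int(tied_idx.size)  # type: ignore[attr-defined]
        h.tied_ids = [masked_ref.records[int(k)].id for k in tied_idx]  # type: ignore[attr-defined]
    return hits


def annotate(
    hits: Sequence[AlignmentHit],
    ref: ReferenceSet,
    read_id: str = "",
    sample_id: str = "",
    adapter_id: str = "",
    umi: str = "",
    seq: str = "",
) -> ReadAnnotation:
    """Merge tied best hits into a single annotation with uniqueness flags.

    Uniqueness at each level is decided over *all* tied transcripts (the
    kernel records them even when more than three tie), so a read never gains
    a unique flag merely because the surplus ties were truncated.
    """
    if not hits:
        raise ValueError("annotate requires at least one hit")
    tied_ids = getattr(hits[0], "tied_ids", [h.transcript_id for h in hits])
    n_tied = getattr(hits[0], "n_tied", len(hits))
    transcripts = list(dict.fromkeys(tied_ids))
    anticodons = frozenset(ref[t].anticodon for t in transcripts)
    amino_acids = frozenset(ref[t].amino_acid for t in transcripts)
    over_tied = n_tied > 3
    unique_transcript = len(transcripts) == 1
    unique_anticodon = len(anticodons) == 1
    unique_amino_acid = len(amino_acids) == 1
    ann = ReadAnnotation(
        read_id=read_id,
        sample_id=sample_id,
        adapter_id=adapter_id,
        umi=umi,
        seq=seq,
        hits_kept=list(hits[:3]),
        unique_transcript=unique_transcript and not over_tied,
        unique_anticodon=unique_anticodon,
        unique_amino_acid=unique_amino_acid,
        over_tied=over_tied,
        anticodons=anticodons,
        amino_acids=amino_acids,
    )
    ann.end_class = classify_3prime_end(ann.best_hit, ref[ann.best_hit.transcript_id], seq)
    return ann


def classify_3prime_end(hit: AlignmentHit, transcript: TranscriptRecord, read_seq: str) -> str:
    """Classify a read's 3' end as ``CCA`` (charged), ``CC`` (uncharged) or ``other``.

    CCA: the read's 3'-terminal base aligns as a match to the transcript's
    final base (the A of CCA) and the last three aligned columns are matches.
    CC: the read's 3'-terminal base aligns as a match to the penultimate C.
    Anything else — truncation by two or more bases, a terminal mismatch or
    gap — is ``other``.  Terminal *matches* are required: masked (N) columns
    do not qualify, which is why the last three reference positions are never
    maskable.
    """
    if not hit.ops:
        return "other"
    ref_end = hit.ref_interval[1]
    query_end = hit.query_interval[1]
    if query_end != len(read_seq):
        return "other"  # read extends past the alignment at the 3' end
    ops = hit.ops
    if ref_end == len(transcript.sequence):
        if len(ops) >= 3 and ops[-3:] == OP_MATCH * 3:
            return "CCA"
        return "other"
    if ref_end == len(transcript.sequence) - 1:
        if ops[-1] == OP_MATCH:
            return "CC"
        return "other"
    return "other"


def align_and_annotate(
    reads,
    masked_ref: ReferenceSet,
    scheme: ScoringScheme = ALIGN_SCHEME,
    min_score: int = 20,
) -> tuple[list[ReadAnnotation], dict]:
    """Align a batch of processed reads and annotate the mapped ones.

    Returns the annotations plus a stats dict (input, mapped, unmapped).
    Deterministic: results depend only on read content and reference order.
    """
    annotations = []
    stats = {"input": 0, "mapped": 0, "unmapped": 0}
    for read in reads:
        stats["input"] += 1
        hits = align_read(read.seq, masked_ref, scheme, min_score)
        if not hits:
            stats["unmapped"] += 1
            continue
        stats["mapped"] += 1
        annotations.append(
            annotate(
                hits,
                masked_ref,
                read_id=read.read_id,
                sample_id=read.sample_id,
                adapter_id=read.adapter_id,
                umi=read.umi,
                seq=read.seq,
            )
        )
    return annotations, stats


def warm_up() -> None:
    """Trigger numba compilation of the alignment kernels."""
    sw_score("ACGT", "ACGT")
    smith_waterman("ACGT", "ACGT")
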