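"""Read preprocessing: pair merging, adapter-barcode assignment, UMI handling.

A merged charge tRNA-Seq read is laid out 5'->3' as::

    [10-nt UMI] [optional non-template bases] [tRNA 3' portion] [barcode + splint context]

Preprocessing (1) collapses read pairs into a single consensus read preserving
the 5' end, (2) assigns each merged read to an adapter barcode by scanning the
3' end for a substring within Hamming distance one of the barcode plus its
splint-complementary context, trimming it, (3) pulls the 10-nt UMI off the 5'
end (5' non-template bases are left in place — local alignment soft-clips
them), and (4) optionally downsamples a sample to a read cap.  The UMI also
drives a sample-quality check comparing observed unique UMIs against the
occupancy expectation.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UMI_LENGTH = 10
#: 9 random nucleotides preceded by a random purine.
DEFAULT_UMI_SPACE = 2 * 4**9  # 524288


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AdapterSpec:
    """A barcoded 3' adapter; matching includes the splint-complementary context."""

    adapter_id: str
    barcode: str
    splint_context: str = ""

    @property
    def full_3p_search_seq(self) -> str:
        return self.barcode + self.splint_context

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError(f"adapter {self.adapter_id}: empty barcode")


def validate_adapters(adapters: Sequence[AdapterSpec]) -> None:
    """Require pairwise barcode Hamming distance > 2 so distance-1 assignment
    is unambiguous.  Unequal-length barcodes are compared over the 5' prefix
    of the longer one."""
    for i, a in enumerate(adapters):
        for b in adapters[i + 1 :]:
            x, y = a.barcode, b.barcode
            n = min(len(x), len(y))
            if hamming(x[:n], y[:n]) <= 2:
                raise ValueError(
                    f"adapters {a.adapter_id} and {b.adapter_id}: barcodes within "
                    f"Hamming distance 2 — distance-1 assignment would be ambiguous"
                )


def load_adapter_table(path: str | Path) -> list[AdapterSpec]:
    """TSV with columns adapter_id, barcode, splint_context (header optional)."""
    adapters = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "adapter_id":
                continue
            splint = parts[2] if len(parts) > 2 else ""
            adapters.append(AdapterSpec(parts[0], parts[1], splint))
    validate_adapters(adapters)
    return adapters


@dataclass
class ProcessedRead:
    """A merged, adapter-trimmed read with its UMI pulled off the 5' end."""

    sample_id: str
    adapter_id: str
    umi: str
    seq: str
    qual: str | None = None
    read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.umi) != UMI_LENGTH:
            raise ValueError(f"UMI must be {UMI_LENGTH} nt, got {len(self.umi)}")


# ---------------------------------------------------------------------------
# Pair merging


@dataclass
class MergeResult:
    merged: str | None
    qual: str | None = None
    reason: str | None = None  # set when rejected


def _trim_adapter_3p(seq: str, qual: str | None, adapter: str, min_prefix: int = 5,
                     max_mismatch_frac: float = 0.1) -> tuple[str, str | None]:
    """Trim a 3' adapter: earliest suffix matching a prefix of ``adapter``."""
    if not adapter:
        return seq, qual
    n = len(seq)
    for start in range(0, n - min_prefix + 1):
        frag = seq[start:]
        ref = adapter[: len(frag)]
        if len(ref) < len(frag):
            continue
        if hamming(frag, ref) <= max_mismatch_frac * len(frag):
            return seq[:start], qual[:start] if qual else None
    return seq, qual


def merge_trim_pairs(
    read1: str,
    read2: str,
    adapter1_seq: str = "",
    adapter2_seq: str = "",
    min_overlap: int = 10,
    min_len: int = 25,
    qual1: str | None = None,
    qual2: str | None = None,
) -> MergeResult:
    """Collapse a read pair into one consensus read preserving the 5' end.

    Adapter read-through is trimmed from each mate's 3' end first; read2 is
    reverse-complemented and the best overlap (>= ``min_overlap``, <= 10%
    mismatches) collapses the pair.  Consensus picks the higher-quality base,
    preferring read1 without qualities.  Merged reads shorter than ``min_len``
    are rejected; the defaults mirror a blunt-end-ligation library (25 nt
    minimum; splint-assisted libraries use 39).
    """
    r1, q1 = _trim_adapter_3p(read1.upper(), qual1, adapter1_seq.upper())
    r2, q2 = _trim_adapter_3p(read2.upper(), qual2, adapter2_seq.upper())
    r2rc = reverse_complement(r2)
    q2rc = q2[::-1] if q2 else None

    best = None  # (score, offset, overlap)
    # offset = position of r2rc start relative to r1 start; may be negative
    for offset in range(-len(r2rc) + min_overlap, len(r1) - min_overlap + 1):
        lo1, hi1 = max(0, offset), min(len(r1), offset + len(r2rc))
        overlap = hi1 - lo1
        if overlap < min_overlap:
            continue
        s1 = r1[lo1:hi1]
        s2 = r2rc[lo1 - offset : hi1 - offset]
        mism = hamming(s1, s2)
        if mism > 0.1 * overlap:
            continue
        score = overlap - 4 * mism
        if best is None or score > best[0]:
            best = (score, offset, overlap)
    if best is None:
        return MergeResult(None, reason="unmergeable")
    _, offset, _ = best
    # consensus over the union, preserving the 5' end (read1 leads)
    start = min(0, offset)
    end = max(len(r1), offset + len(r2rc))
    out_seq = []
    out_qual = [] if (q1 and q2rc) else None
    for pos in range(start, end):
        b1 = r1[pos] if 0 <= pos < len(r1) else None
        p2 = pos - offset
        b2 = r2rc[p2] if 0 <= p2 < len(r2rc) else None
        if b1 is not None and b2 is not None:
            if b1 == b2:
                base = b1
            elif q1 and q2rc and q2rc[p2] > q1[pos]:
                base = b2
            else:
                base = b1  # prefer read1 (preserve the 5'-called base)
        else:
            base = b1 if b1 is not None else b2
        out_seq.append(base)
        if out_qual is not None:
            c1 = q1[pos] if (b1 is not None) else None
            c2 = q2rc[p2] if (b2 is not None) else None
            out_qual.append(max(x for x in (c1, c2) if x is not None))
    merged = "".join(out_seq)
    if len(merged) < min_len:
        return MergeResult(None, reason="too_short")
    return MergeResult(merged, qual="".join(out_qual) if out_qual else None)


# ---------------------------------------------------------------------------
# Adapter-barcode assignment


def assign_adapter_barcode(
    merged_read: str,
    adapters: Sequence[AdapterSpec],
    window_slack: int = 4,
) -> tuple[str | None, str, str]:
    """Assign a merged read to an adapter barcode and trim the matched region.

    The 3'-most substring within Hamming distance one of an adapter's
    ``barcode + splint_context`` is searched inside a bounded 3' window
    (the last ``len(search) + window_slack`` bases).  Returns
    ``(adapter_id, trimmed_read, status)`` with status one of ``assigned``,
    ``ambiguous`` (>= 2 adapters match) or ``unmatched``; on failure
    adapter_id is None and the read is returned untrimmed.
    """
    merged_read = merged_read.upper()
    matches: dict[str, int] = {}  # adapter_id -> 3'-most match start
    for ad in adapters:
        search = ad.full_3p_search_seq.upper()
        k = len(search)
        if k == 0 or len(merged_read) < k:
            continue
        window_start = max(0, len(merged_read) - k - window_slack)
        hit_start = None
        for start in range(len(merged_read) - k, window_start - 1, -1):
            if hamming(merged_read[start : start + k], search) <= 1:
                hit_start = start
                break  # 3'-most first because we scan right-to-left
        if hit_start is not None:
            matches[ad.adapter_id] = hit_start
    if not matches:
        return None, merged_read, "unmatched"
    if len(matches) > 1:
        return None, merged_read, "ambiguous"
    adapter_id, start = next(iter(matches.items()))
    return adapter_id, merged_read[:start], "assigned"


def extract_umi(
    trimmed_read: str,
    sample_id: str = "",
    adapter_id: str = "",
    qual: str | None = None,
    read_id: str = "",
) -> ProcessedRead | None:
    """Pull the 10-nt UMI off the 5' end; returns None for reads <= 10 nt."""
    if len(trimmed_read) <= UMI_LENGTH:
        return None
    return ProcessedRead(
        sample_id=sample_id,
        adapter_id=adapter_id,
        umi=trimmed_read[:UMI_LENGTH],
        seq=trimmed_read[UMI_LENGTH:],
        qual=qual[UMI_LENGTH:] if qual else None,
        read_id=read_id,
    )


# ---------------------------------------------------------------------------
# Downsampling and UMI QC


def downsample(reads: Sequence, cap: int = 2_000_000, seed: int = 0) -> list:
    """Uniform random subset of size ``cap`` (reservoir sampling); identity if
    the sample is already within the cap.  Reproducible for a fixed seed."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    reads = list(reads)
    if len(reads) <= cap:
        return reads
    rng = np.random.default_rng(seed)
    reservoir = reads[:cap]
    for idx in range(cap, len(reads)):
        j = rng.integers(0, idx + 1)
        if j < cap:
            reservoir[j] = reads[idx]
    return reservoir


def umi_space_size(n_random_nt: int = 9, leading_purine: bool = True) -> int:
    """Number of possible UMI sequences: 4^n, doubled for a leading purine."""
    if n_random_nt < 0:
        raise ValueError("n_random_nt must be >= 0")
    size = 4**n_random_nt
    return 2 * size if leading_purine else size


def expected_unique_umis(n_reads: int, umi_space: int, literal_roles: bool = False) -> float:
    """Expected number of distinct UMIs among ``n_reads`` uniform draws.

    The occupancy expectation ``k * (1 - ((k-1)/k)^n)`` with ``n`` reads and
    ``k`` possible UMIs.  ``literal_roles=True`` evaluates the same expression
    with the roles of n and k exchanged, ``n * (1 - ((n-1)/n)^k)`` — the two
    agree in the sparse regime (n << k) but only the occupancy form matches
    simulation when n approaches or exceeds k.
    """
    if umi_space < 1:
        raise ValueError("umi_space must be >= 1")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return 0.0
    if literal_roles:
        n, k = umi_space, n_reads  # printed-role variant
    else:
        n, k = n_reads, umi_space
    if k == 1:
        return 1.0
    return k * (1.0 - math.exp(n * math.log1p(-1.0 / k)))


@dataclass
class UmiQc:
    """Observed vs expected unique-UMI counts for one sample."""

    n_reads: int
    umi_space: int
    observed_unique: int
    expected_unique: float

    @classmethod
    def from_reads(cls, reads: Iterable[ProcessedRead], umi_space: int = DEFAULT_UMI_SPACE) -> "UmiQc":
        umis = [r.umi for r in reads]
        return cls(
            n_reads=len(umis),
            umi_space=umi_space,
            observed_unique=len(set(umis)),
            expected_unique=expected_unique_umis(len(umis), umi_space),
        )


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-tolerant)


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, seq, qual) triples."""
    with open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].split()[0], seq, qual


def write_processed_fastq(reads: Iterable[ProcessedRead], path: str | Path) -> None:
    """Write processed reads with the UMI preserved in the header (UMI:Z: tag)."""
    with open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.read_id} UMI:Z:{r.umi}\n{r.seq}\n+\n{qual}\n")


def preprocess_sample(
    merged_reads: Iterable[tuple[str, str, str]],
    adapters: Sequence[AdapterSpec],
    sample_id: str,
    min_len: int = 25,
    downsample_cap: int = 2_000_000,
    seed: int = 0,
) -> tuple[list[ProcessedRead], dict]:
    """Run barcode assignment + UMI extraction over merged reads of one sample.

    Returns the processed reads and a stats dict satisfying the conservation
    invariant: assigned + ambiguous + unmatched + length_rejected == input.
    """
    validate_adapters(adapters)
    stats = {
        "input": 0,
        "assigned": 0,
        "ambiguous": 0,
        "unmatched": 0,
        "length_rejected": 0,
        "downsampled_to": None,
    }
    processed: list[ProcessedRead] = []
    for read_id, seq, qual in merged_reads:
        stats["input"] += 1
        if len(seq) < min_len:
            stats["length_rejected"] += 1
            continue
        adapter_id, trimmed, status = assign_adapter_barcode(seq, adapters)
        if status != "assigned":
            stats[status] += 1
            continue
        pr = extract_umi(trimmed, sample_id=sample_id, adapter_id=adapter_id,
                         qual=qual, read_id=read_id)
        if pr is None:
            stats["length_rejected"] += 1
            continue
        stats["assigned"] += 1
        processed.append(pr)
    if len(processed) > downsample_cap:
        processed = downsample(processed, cap=downsample_cap, seed=seed)
        stats["downsampled_to"] = downsample_cap
    return processed, stats
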