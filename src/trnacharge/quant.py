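"""Charge and relative-expression tables at transcript, anticodon and amino-acid level.

Charge is the percentage of confidently mapped molecules retaining the full
CCA end: ``100 * n_cca / (n_cca + n_cc)``, computed from *uncorrected* read
counts (it is a ratio, so PCR duplicates cancel).  Relative expression is
reads per million (RPM) over *UMI-corrected* counts: reads with identical
sequence and UMI count once.

Aggregation levels apply nested uniqueness filters: transcript-level rows
require a unique transcript annotation; anticodon (codon) level only a unique
anticodon; amino-acid level only a unique amino acid.  Reads with an ``other``
3'-end class (truncated or mismatched ends) are excluded from charge but kept
in RPM — they are real molecules, just uninformative about aminoacylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import pandas as pd

from trnacharge.align import ReadAnnotation
from trnacharge.reference import ReferenceSet

LEVELS = ("transcript", "anticodon", "amino_acid")


def _group_key(ann: ReadAnnotation, level: str) -> str | None:
    """Group id for an annotation at a level, or None if it fails the
    level's uniqueness filter."""
    if level == "transcript":
        if not ann.unique_transcript:
            return None
        return ann.best_hit.transcript_id
    if level == "anticodon":
        if not ann.unique_anticodon:
            return None
        return next(iter(ann.anticodons))
    if level == "amino_acid":
        if not ann.unique_amino_acid:
            return None
        return next(iter(ann.amino_acids))
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def umi_collapse_counts(annotations: Iterable[ReadAnnotation], level: str) -> dict[str, int]:
    """UMI-corrected counts per group: identical (sequence, UMI) pairs within a
    sample count once; the level's uniqueness filter applies."""
    seen: set[tuple] = set()
    counts: dict[str, int] = {}
    for ann in annotations:
        gid = _group_key(ann, level)
        if gid is None:
            continue
        key = (ann.sample_id, gid, ann.seq, ann.umi)
        if key in seen:
            continue
        seen.add(key)
        counts[gid] = counts.get(gid, 0) + 1
    return counts


@dataclass
class ChargeRow:
    group_id: str
    n_cca: int
    n_cc: int
    charge_pct: float | None  # None when n_cca + n_cc == 0
    low_coverage: bool


def charge_table(
    annotations: Iterable[ReadAnnotation],
    level: str = "transcript",
    min_reads: int = 100,
) -> pd.DataFrame:
    """Per-group CCA/CC tallies and charge percentage over raw read counts.

    Groups with fewer than ``min_reads`` informative reads are flagged
    ``low_coverage`` (flagged, never dropped).  ``end_class == "other"`` reads
    contribute to neither numerator nor denominator.
    """
    tallies: dict[str, list[int]] = {}
    for ann in annotations:
        gid = _group_key(ann, level)
        if gid is None or ann.end_class == "other":
            continue
        cca, cc = tallies.setdefault(gid, [0, 0])
        if ann.end_class == "CCA":
            tallies[gid][0] += 1
        else:
            tallies[gid][1] += 1
    rows = []
    for gid in sorted(tallies):
        n_cca, n_cc = tallies[gid]
        total = n_cca + n_cc
        rows.append(
            {
                "group": gid,
                "n_cca": n_cca,
                "n_cc": n_cc,
                "charge_pct": 100.0 * n_cca / total if total else None,
                "low_coverage": total < min_reads,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_cca", "n_cc", "charge_pct", "low_coverage"])


def rpm_table(
    annotations: Sequence[ReadAnnotation],
    level: str = "transcript",
    ref: ReferenceSet | None = None,
    exclude_spikeins_from_denominator: bool = True,
) -> pd.DataFrame:
    """Reads-per-million over UMI-corrected counts.

    Spike-in transcripts (when ``ref`` is given and the flag is set) get their
    own rows but are excluded from the cellular-tRNA RPM denominator; their
    rpm is reported relative to that same denominator so spike-in recovery is
    comparable across samples.  RPM values over cellular groups sum to 1e6.
    """
    counts = umi_collapse_counts(annotations, level)
    if not counts:
        warnings.warn("rpm_table: zero mapped reads at this level")
        return pd.DataFrame(columns=["group", "umi_count", "rpm", "is_spikein"])

    def is_spike(gid: str) -> bool:
        if ref is None or level != "transcript":
            return False
        return gid in ref and ref[gid].is_spikein

    denom = sum(
        c for g, c in counts.items() if not (exclude_spikeins_from_denominator and is_spike(g))
    )
    rows = []
    for gid in sorted(counts):
        rows.append(
            {
                "group": gid,
                "umi_count": counts[gid],
                "rpm": 1e6 * counts[gid] / denom if denom else float("nan"),
                "is_spikein": is_spike(gid),
            }
        )
    return pd.DataFrame(rows)
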