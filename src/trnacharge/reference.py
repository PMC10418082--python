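"""tRNA transcript reference handling: loading, validation, deduplication, masking.

Mature tRNA sequences carry an invariant 3'-terminal CCA; the charge assay
depends on it (charged molecules are sequenced with CCA, uncharged with CC), so
the reference is stored as mature sequences including the CCA and a helper can
append it where a genomic prediction lacks it.  High-misincorporation positions
are masked to ``N`` so that alignment scores are not penalised by
modification-induced errors; a :class:`MaskSet` records those positions
(0-based) and round-trips through a TSV file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# GtRNAdb-style mature tRNA name, e.g. "tRNA-Lys-TTT-3-1" or
# "Homo_sapiens_tRNA-Ala-AGC-1-1".  Amino acid may be "iMet", "SeC", "Und" etc.
_GTRNADB_RE = re.compile(
    r"tRNA-(?P<aa>[A-Za-z]{2,4})-(?P<anticodon>[ACGTN]{3})(?:-[\w.]+)*", re.IGNORECASE
)

_SEQ_RE = re.compile(r"^[ACGTN]+$")


def parse_gtrnadb_name(name: str) -> tuple[str, str]:
    """Parse amino acid and anticodon from a GtRNAdb-style transcript name.

    Returns ``("Und", "NNN")`` when the name does not follow the
    ``tRNA-<AA>-<anticodon>-<family>-<copy>`` convention (spike-ins, custom
    oligos); such records are kept, never dropped.
    """
    m = _GTRNADB_RE.search(name)
    if m is None:
        return "Und", "NNN"
    return m.group("aa"), m.group("anticodon").upper()


@dataclass(frozen=True)
class TranscriptRecord:
    """One mature tRNA transcript (or spike-in control) in the reference."""

    id: str
    sequence: str
    amino_acid: str = "Und"
    anticodon: str = "NNN"
    is_spikein: bool = False
    is_mito: bool = False

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise ValueError(
                f"transcript {self.id!r}: sequence must match [ACGTN]+, got "
                f"{self.sequence[:20]!r}..."
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """Ordered, id-indexed collection of unique transcript records.

    Invariants: ids are unique and no two records share an identical sequence
    (use :func:`load_reference` or :meth:`deduplicated` to enforce the
    latter).
    """

    def __init__(self, records: Iterable[TranscriptRecord]):
        self.records: list[TranscriptRecord] = list(records)
        self._index: dict[str, TranscriptRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                if self._index[rec.id].sequence != rec.sequence:
                    raise ValueError(
                        f"duplicate id {rec.id!r} with differing sequences"
                    )
                raise ValueError(f"duplicate id {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self._index[transcript_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def deduplicated(self) -> "ReferenceSet":
        """Drop records whose sequence was already seen; first id wins (order-stable)."""
        seen: dict[str, str] = {}
        kept = []
        for rec in self.records:
            if rec.sequence in seen:
                logger.info(
                    "dedup: dropping %s (identical to %s)", rec.id, seen[rec.sequence]
                )
                continue
            seen[rec.sequence] = rec.id
            kept.append(rec)
        return ReferenceSet(kept)

    def to_fasta(self, path: str | Path) -> None:
        """Write the reference as single-line FASTA."""
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return self.records == other.records


def load_reference(
    fasta_path: str | Path,
    spikein_fastas: Iterable[str | Path] = (),
    name_parser: Callable[[str], tuple[str, str]] | None = None,
) -> ReferenceSet:
    """Load a tRNA transcript reference FASTA, deduplicate, append spike-ins.

    Parameters
    ----------
    fasta_path
        Mature (spliced) tRNA sequences; wrapped or single-line FASTA accepted.
    spikein_fastas
        Extra FASTAs whose records are appended after deduplication and
        flagged ``is_spikein``.
    name_parser
        Maps a record id to ``(amino_acid, anticodon)``.  Defaults to the
        GtRNAdb convention; unparseable names are flagged ``"Und"``.
    """
    parser = name_parser or parse_gtrnadb_name
    records = _read_fasta(fasta_path, parser, is_spikein=False)
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    ref = ReferenceSet(records).deduplicated()
    spikes: list[TranscriptRecord] = []
    for sp_path in spikein_fastas:
        spikes.extend(_read_fasta(sp_path, parser, is_spikein=True))
    return ReferenceSet(ref.records + spikes)


def _read_fasta(
    path: str | Path,
    parser: Callable[[str], tuple[str, str]],
    is_spikein: bool,
) -> list[TranscriptRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        aa, anticodon = parser(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(
            TranscriptRecord(
                id=rec.id,
                sequence=seq,
                amino_acid=aa,
                anticodon=anticodon,
                is_spikein=is_spikein,
                is_mito="mito" in rec.id.lower() or rec.id.lower().startswith("mt"),
            )
        )
    return records


def ensure_cca(ref: ReferenceSet) -> ReferenceSet:
    """Return a reference in which every sequence ends with ``CCA``.

    Sequences already ending in CCA pass through unchanged; others get the
    missing suffix appended.  A sequence ending in ``CC`` is ambiguous (it may
    be a truncated CCA or a genomic coincidence): the full ``CCA`` is appended
    and a warning logged.
    """
    out = []
    for rec in ref:
        seq = rec.sequence
        if seq.endswith("CCA"):
            out.append(rec)
            continue
        if seq.endswith("CC"):
            logger.warning(
                "transcript %s ends in 'CC' (ambiguous); appending full 'CCA'", rec.id
            )
            new_seq = seq + "CCA"
        elif seq.endswith("C"):
            new_seq = seq + "CA"
        else:
            new_seq = seq + "CCA"
        logger.info("transcript %s: appended %s to reach CCA end", rec.id, new_seq[len(seq):])
        out.append(replace(rec, sequence=new_seq))
    return ReferenceSet(out)


class MaskSet(dict):
    """Mapping of transcript id -> set of 0-based positions to mask to N."""

    def __init__(self, mapping: Mapping[str, Iterable[int]] | None = None):
        super().__init__()
        if mapping:
            for tid, positions in mapping.items():
                self[tid] = set(int(p) for p in positions)

    def n_masked(self) -> int:
        return sum(len(v) for v in self.values())

    def copy(self) -> "MaskSet":
        return MaskSet({tid: set(pos) for tid, pos in self.items()})

    def to_tsv(self, path: str | Path) -> None:
        """transcript_id <tab> comma-separated 0-based positions, one line each."""
        with open(path, "w") as fh:
            for tid in sorted(self):
                if self[tid]:
                    fh.write(f"{tid}\t{','.join(str(p) for p in sorted(self[tid]))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaskSet":
        mask = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tid, _, pos_str = line.partition("\t")
                mask[tid] = {int(p) for p in pos_str.split(",") if p}
        return mask

    def __eq__(self, other: object) -> bool:
        if isinstance(other, (MaskSet, dict)):
            return {k: set(v) for k, v in self.items() if v} == {
                k: set(v) for k, v in other.items() if v
            }
        return NotImplemented

    __hash__ = None  # type: ignore[assignment]


def apply_mask(ref: ReferenceSet, mask: MaskSet) -> ReferenceSet:
    """Replace masked positions with ``N``; the input set is left unmodified.

    Raises
    ------
    ValueError
        If a masked position falls outside its transcript, naming both.
    """
    out = []
    for rec in ref:
        positions = mask.get(rec.id, ())
        if not positions:
            out.append(rec)
            continue
        seq = list(rec.sequence)
        for pos in positions:
            if not 0 <= pos < len(seq):
                raise ValueError(
                    f"mask position {pos} out of range for transcript "
                    f"{rec.id!r} (length {len(seq)})"
                )
            seq[pos] = "N"
        out.append(replace(rec, sequence="".join(seq)))
    return ReferenceSet(out)
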