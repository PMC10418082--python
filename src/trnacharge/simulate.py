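"""Synthetic charge tRNA-Seq data with complete ground truth.

Emulates the assay's data-generating process so every analysis stage is
testable without external sequencing data:

* a reference of tRNA-like transcript families (near-identical members,
  GtRNAdb-style names, invariant 3' CCA);
* merged reads laid out UMI + tRNA 3'-portion + adapter barcode/splint
  context, with per-transcript true charge (CCA vs CC ends), geometric RT
  falloff truncating the 5' side, modification hotspots injecting mismatches /
  gaps / extra falloff, uniform sequencing error, and optional UMI-level
  duplication (PCR duplicates);
* titration measurements drawn from the mixture model plus Gaussian noise and
  optional per-adapter bias;
* decay time-series drawn from the first-order decay model plus Gaussian
  noise, clipped to [0, 100].

Every generator is deterministic given a seed and returns (or serialises) the
truth needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trnacharge.models import (
    DECAY_TIMEPOINTS_MIN,
    TITRATION_RATIOS,
    decay_value,
    predict_titration_charge,
)
from trnacharge.preprocess import AdapterSpec, ProcessedRead
from trnacharge.reference import ReferenceSet, TranscriptRecord

_BASES = np.array(list("ACGT"))
_PURINES = np.array(list("AG"))

#: Toy adapter table used throughout the synthetic suite.  Barcodes are
#: pairwise Hamming distance > 2 so distance-1 assignment is unambiguous.
DEFAULT_ADAPTERS = (
    AdapterSpec("I1Sp", "ACGTC", "GGATTCG"),
    AdapterSpec("I2Sp", "CAATG", "GGATTCG"),
    AdapterSpec("I3Sp", "TGCGA", "GGATTCG"),
    AdapterSpec("A1", "GTTACCGT", "GGATTCG"),
)

ANTICODONS = (
    "TTT", "AGC", "CAT", "GAA", "TGG", "GCC", "CTG", "AAC",
    "GTA", "TCC", "CCA", "ATG", "GGT", "TAC", "CGA", "ACG",
)
AMINO_ACIDS = (
    "Lys", "Ala", "Met", "Phe", "Pro", "Gly", "Gln", "Val",
    "Tyr", "Gly2", "Trp", "His", "Thr", "Val2", "Ser", "Arg",
)


@dataclass
class Hotspot:
    """A modified position: probabilities of mismatch, gap and RT falloff."""

    position: int
    mismatch_prob: float = 0.0
    gap_prob: float = 0.0
    falloff_prob: float = 0.0


@dataclass
class SimTruth:
    """Ground truth behind a simulated read set."""

    charge: Mapping[str, float]  # transcript -> P(read ends CCA)
    abundance: Mapping[str, float]  # transcript -> weight (sums to 1)
    hotspots: Mapping[str, Sequence[Hotspot]] = field(default_factory=dict)
    adapter_bias_pp: Mapping[str, float] = field(default_factory=dict)
    seq_error: float = 0.001
    falloff_per_base: float = 0.005  # geometric 5'-ward RT falloff
    min_tail: int = 30  # minimum 3' bases retained before falloff applies
    duplicate_rate: float = 0.0  # probability a read is an exact PCR duplicate
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript": tid, "true_charge": self.charge[tid], "abundance": self.abundance[tid]}
            for tid in self.charge
        ]
        return pd.DataFrame(rows)


def simulate_reference(
    n_families: int = 4,
    members_per_family: int = 2,
    length_range: tuple[int, int] = (72, 78),
    divergence: float = 0.06,
    seed: int = 0,
) -> tuple[ReferenceSet, dict[str, list[str]]]:
    """Families of near-identical CCA-ending transcripts with GtRNAdb names.

    Family members share a common ancestor sequence with point mutations at
    rate ``divergence`` (the 3' CCA never mutates).  With divergence 0 the
    members are byte-identical apart from their ids — dedup would collapse
    them, which is exactly what tie tests exploit.
    Returns the reference and a family map anticodon -> member ids.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("n_families and members_per_family must be positive")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    family_map: dict[str, list[str]] = {}
    for fam in range(n_families):
        anticodon = ANTICODONS[fam % len(ANTICODONS)]
        aa = AMINO_ACIDS[fam % len(AMINO_ACIDS)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(_BASES, size=length - 3))
        members = []
        for copy in range(members_per_family):
            seq = list(body)
            if divergence > 0:
                for i in range(len(seq)):
                    if rng.random() < divergence:
                        seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            tid = f"tRNA-{aa}-{anticodon}-{fam + 1}-{copy + 1}"
            members.append(tid)
            records.append(
                TranscriptRecord(
                    id=tid,
                    sequence="".join(seq) + "CCA",
                    amino_acid=aa,
                    anticodon=anticodon,
                )
            )
        family_map[anticodon] = members
    return ReferenceSet(records), family_map


def _mutate(base: str, rng) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def random_umi(rng) -> str:
    return str(rng.choice(_PURINES)) + "".join(rng.choice(_BASES, size=9))


def simulate_reads(
    ref: ReferenceSet,
    truth: SimTruth,
    n_reads: int,
    adapters: Sequence[AdapterSpec] = DEFAULT_ADAPTERS,
    sample_id: str = "sim",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Draw merged reads; returns (FASTQ-style triples, per-read truth table).

    Each read: transcript by abundance; CCA end with probability equal to the
    transcript's true charge, else CC; 5' truncation by per-base geometric
    falloff plus hotspot falloff; hotspot mismatches/gaps; uniform sequencing
    error; purine-led 10-nt UMI; adapter barcode + splint context appended 3'.
    """
    rng = np.random.default_rng(truth.seed)
    tids = list(truth.abundance)
    weights = np.array([truth.abundance[t] for t in tids], dtype=float)
    weights = weights / weights.sum()
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    i = 0
    prev: tuple | None = None
    while len(reads) < n_reads:
        if prev is not None and truth.duplicate_rate > 0 and rng.random() < truth.duplicate_rate:
            rid = f"read{i}"
            reads.append((rid, prev[0], "I" * len(prev[0])))
            truth_rows.append({**prev[1], "read_id": rid, "duplicate": True})
            i += 1
            continue
        tid = tids[int(rng.choice(len(tids), p=weights))]
        rec = ref[tid]
        seq = rec.sequence
        is_cca = bool(rng.random() < truth.charge[tid])
        trna = seq if is_cca else seq[:-1]
        # 5' truncation: walk 3'->5'; beyond min_tail each base may stop RT
        hotspots = {h.position: h for h in truth.hotspots.get(tid, ())}
        start = 0
        for pos in range(len(trna) - truth.min_tail - 1, -1, -1):
            p_stop = truth.falloff_per_base
            if pos in hotspots:
                p_stop = 1.0 - (1.0 - p_stop) * (1.0 - hotspots[pos].falloff_prob)
            if rng.random() < p_stop:
                start = pos + 1
                break
        portion = list(trna[start:])
        # hotspot mismatches/gaps (reference coordinates)
        offset = start
        out = []
        for k, base in enumerate(portion):
            pos = offset + k
            h = hotspots.get(pos)
            if h is not None and rng.random() < h.gap_prob:
                continue  # base deleted by RT
            if h is not None and rng.random() < h.mismatch_prob:
                out.append(_mutate(base, rng))
            else:
                out.append(base)
        # uniform sequencing error
        for k in range(len(out)):
            if rng.random() < truth.seq_error:
                out[k] = _mutate(out[k], rng)
        adapter = adapters[int(rng.integers(len(adapters)))]
        umi = random_umi(rng)
        full = umi + "".join(out) + adapter.full_3p_search_seq
        rid = f"read{i}"
        row = {
            "read_id": rid,
            "transcript": tid,
            "cca": is_cca,
            "ref_start": start,
            "adapter": adapter.adapter_id,
            "umi": umi,
            "duplicate": False,
        }
        reads.append((rid, full, "I" * len(full)))
        truth_rows.append(row)
        prev = (full, {k: v for k, v in row.items() if k != "read_id"})
        i += 1
    return reads, pd.DataFrame(truth_rows)


def uniform_truth(
    ref: ReferenceSet,
    charge: float | Mapping[str, float] = 0.7,
    seed: int = 0,
    **kwargs,
) -> SimTruth:
    """Convenience SimTruth: equal abundance, shared or per-transcript charge."""
    tids = ref.ids()
    if isinstance(charge, (int, float)):
        charge_map = {t: float(charge) for t in tids}
    else:
        charge_map = dict(charge)
    return SimTruth(
        charge=charge_map,
        abundance={t: 1.0 / len(tids) for t in tids},
        seed=seed,
        **kwargs,
    )


def simulate_titration(
    transcripts: Sequence[str],
    f_true: Mapping[str, float],
    t_a_true: Mapping[str, float],
    t_b_true: Mapping[str, float],
    ratios: Sequence[float] = TITRATION_RATIOS,
    n_reps: int = 4,
    noise_sd: float = 1.0,
    adapter_bias_pp: Mapping[str, float] | None = None,
    adapters: Sequence[str] = ("I1Sp", "I2Sp", "I3Sp", "A1"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Titration measurements from the mixture model plus noise and bias.

    ``ratios`` must include the endpoints 100 and 0 (they define T_A/T_B
    downstream).  Each (transcript, ratio, replicate) measurement is the
    model prediction plus N(0, noise_sd) plus the replicate's adapter bias,
    clipped to [0, 100].  Returns (measurements, truth frame).
    """
    if 100.0 not in ratios or 0.0 not in ratios:
        raise ValueError("ratios must include the endpoints 100 and 0")
    rng = np.random.default_rng(seed)
    bias = adapter_bias_pp or {}
    rows = []
    for tid in transcripts:
        for p in ratios:
            pred = float(
                predict_titration_charge(p, t_a_true[tid], t_b_true[tid], f_true[tid])
            )
            for rep in range(n_reps):
                adapter = adapters[rep % len(adapters)]
                val = pred + bias.get(adapter, 0.0)
                if noise_sd > 0:
                    val += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "transcript": tid,
                        "ratio_p": float(p),
                        "replicate": rep,
                        "adapter": adapter,
                        "measured_charge": float(np.clip(val, 0.0, 100.0)),
                    }
                )
    truth = pd.DataFrame(
        [
            {"transcript": t, "F_true": f_true[t], "T_A_true": t_a_true[t], "T_B_true": t_b_true[t]}
            for t in transcripts
        ]
    )
    return pd.DataFrame(rows), truth


def simulate_decay(
    params_per_group: Mapping[str, tuple[float, float, float]],
    timepoints: Sequence[float] = DECAY_TIMEPOINTS_MIN,
    n_reps: int = 4,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decay series: three-parameter first-order decay plus Gaussian noise.

    ``params_per_group`` maps group -> (N0, t_half_min, N_inf).  Charges are
    clipped to [0, 100].  Returns (series, truth frame).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gid, (n0, t_half, n_inf) in params_per_group.items():
        for t in timepoints:
            base = float(decay_value(t, n0, t_half, n_inf))
            for rep in range(n_reps):
                val = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "group": gid,
                        "time_min": float(t),
                        "replicate": rep,
                        "charge": float(np.clip(val, 0.0, 100.0)),
                    }
                )
    truth = pd.DataFrame(
        [
            {"group": g, "N0_true": v[0], "t_half_true": v[1], "N_inf_true": v[2]}
            for g, v in params_per_group.items()
        ]
    )
    return pd.DataFrame(rows), truth


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
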