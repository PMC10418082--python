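"""End-to-end orchestration: preprocess -> align -> quantify/profile.

A :class:`RunConfig` collects every knob (paths, scoring, thresholds, seed),
is validated before any compute, and is serialised verbatim into the output
directory so a run is reproducible from its own artifacts.  Outputs are TSVs
(charge, RPM, profiles, masks) plus a machine-readable ``summary.json`` with
per-stage read counts satisfying the conservation invariant.  Results are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from trnacharge import __version__
from trnacharge.align import ALIGN_SCHEME, ScoringScheme, align_and_annotate
from trnacharge.maskopt import MaskingParams, grid_report, grid_search, iterate_masking
from trnacharge.modprofile import build_profiles, realign_annotations
from trnacharge.preprocess import (
    DEFAULT_UMI_SPACE,
    AdapterSpec,
    UmiQc,
    load_adapter_table,
    preprocess_sample,
    read_fastq,
)
from trnacharge.quant import LEVELS, charge_table, rpm_table
from trnacharge.reference import MaskSet, ReferenceSet, apply_mask, ensure_cca, load_reference

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    reads_fastq: str
    reference_fasta: str
    adapter_table: str
    output_dir: str
    sample_id: str = "sample"
    mask_tsv: str | None = None
    min_len: int = 25
    min_score: int = 20
    downsample_cap: int = 2_000_000
    min_charge_reads: int = 100
    umi_space: int = DEFAULT_UMI_SPACE
    scoring: ScoringScheme = field(default_factory=lambda: ALIGN_SCHEME)
    seed: int = 0

    def validate(self) -> None:
        for name in ("reads_fastq", "reference_fasta", "adapter_table"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if self.mask_tsv and not Path(self.mask_tsv).exists():
            raise FileNotFoundError(f"mask_tsv: {self.mask_tsv} does not exist")
        if self.min_len < 1 or self.min_score < 1 or self.downsample_cap < 1:
            raise ValueError("min_len, min_score and downsample_cap must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        # analysis-relevant parameters only: where outputs land must not
        # change what they contain
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# trnacharge {__version__} | config {config.config_hash} | seed {config.seed}\n"
        "# charge on 0-100 scale; fractions on 0-1; positions 0-based\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Full run: preprocess, align, quantify, profile.  Returns the summary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))

    ref = ensure_cca(load_reference(config.reference_fasta))
    mask = MaskSet.from_tsv(config.mask_tsv) if config.mask_tsv else MaskSet()
    masked_ref = apply_mask(ref, mask)

    adapters = load_adapter_table(config.adapter_table)
    reads, pre_stats = preprocess_sample(
        read_fastq(config.reads_fastq),
        adapters,
        sample_id=config.sample_id,
        min_len=config.min_len,
        downsample_cap=config.downsample_cap,
        seed=config.seed,
    )
    qc = UmiQc.from_reads(reads, umi_space=config.umi_space)

    annotations, align_stats = align_and_annotate(
        reads, masked_ref, config.scoring, config.min_score
    )

    for level in LEVELS:
        _write_tsv(
            charge_table(annotations, level, min_reads=config.min_charge_reads),
            out / f"charge_{level}.tsv",
            config,
        )
        _write_tsv(rpm_table(annotations, level, ref=ref), out / f"rpm_{level}.tsv", config)

    events = realign_annotations(annotations, ref)
    _write_tsv(build_profiles(events, ref), out / "profiles.tsv", config)

    n_mapped = align_stats["mapped"]
    summary = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "preprocess": pre_stats,
        "align": align_stats,
        "umi_qc": dataclasses.asdict(qc),
        "pct_mapped": 100.0 * n_mapped / align_stats["input"] if align_stats["input"] else 0.0,
        "pct_multi_anticodon": (
            100.0 * sum(1 for a in annotations if not a.unique_anticodon) / n_mapped
            if n_mapped
            else None
        ),
        "mask_size": mask.n_masked(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_mask_optimization(
    reads: Sequence,
    ref: ReferenceSet,
    grid: Sequence[MaskingParams] | None,
    output_dir: str | Path,
    min_score: int = 20,
) -> MaskSet:
    """Grid-search masking parameters and write mask + report artifacts."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    best, results = grid_search(reads, ref, grid, min_score=min_score)
    report = grid_report(results)
    report.to_csv(out / "grid_report.tsv", sep="\t", index=False)
    best.mask.to_tsv(out / "mask.tsv")
    apply_mask(ref, best.mask).to_fasta(out / "masked_reference.fasta")
    logger.info(
        "best mask: %d positions, %.2f%% multi-anticodon, %.2f%% mapped",
        best.mask_size,
        best.pct_multi_anticodon,
        best.pct_mapped,
    )
    return best.mask
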