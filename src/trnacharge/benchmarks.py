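"""Self-contained recovery benchmarks on synthetic data with known truth.

Each function generates its inputs from a seed, runs the relevant pipeline
stages, and measures how well the known ground truth is recovered.  They are
the basis of the acceptance checks and of the reproducibility script; problem
sizes default to the study conditions the method was characterised under
(50,000 reads over an 8-transcript reference for charge recovery; an
11-timepoint x 4-replicate decay design with 1000 bootstrap iterates; 6
interior titration ratios x 4 replicates).
"""

from __future__ import annotations

import numpy as np

from trnacharge.align import ALIGN_SCHEME, REALIGN_SCHEME, align_and_annotate, sw_score
from trnacharge.maskopt import MaskingParams, evaluate_mask, grid_search
from trnacharge.models import DecayModel, TitrationModel
from trnacharge.preprocess import (
    DEFAULT_UMI_SPACE,
    expected_unique_umis,
    preprocess_sample,
    umi_space_size,
)
from trnacharge.quant import charge_table, rpm_table
from trnacharge.reference import MaskSet, ReferenceSet, TranscriptRecord
from trnacharge.simulate import (
    DEFAULT_ADAPTERS,
    Hotspot,
    simulate_decay,
    simulate_reads,
    simulate_reference,
    simulate_titration,
    uniform_truth,
)

#: Per-transcript true charges used in the end-to-end recovery benchmark.
CHARGE_LEVELS = (0.0, 0.25, 0.5, 0.75, 0.95, 0.25, 0.5, 0.75)


def oracle_local_score(query: str, ref: str, scheme) -> int:
    """Independent exhaustive local-alignment DP (no affine gap states; every
    gap length enumerated, O(n^3)).  Used only to cross-check the production
    kernel."""
    m, n = len(query), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if ref[j - 1] == "N":
                sub = scheme.n_score
            elif query[i - 1] == ref[j - 1]:
                sub = scheme.match
            else:
                sub = scheme.mismatch
            v = max(0, H[i - 1][j - 1] + sub)
            for g in range(1, j + 1):
                v = max(v, H[i][j - g] - (scheme.gap_open + scheme.gap_extend * (g - 1)))
            for g in range(1, i + 1):
                v = max(v, H[i - g][j] - (scheme.gap_open + scheme.gap_extend * (g - 1)))
            H[i][j] = v
            best = max(best, v)
    return best


def alignment_oracle_benchmark(seed: int, n_pairs: int = 200) -> dict:
    """Score agreement between the kernel and the exhaustive oracle on random
    query/reference pairs (lengths <= 30), plain and N-masked, under both the
    primary and the realignment scoring schemes."""
    rng = np.random.default_rng(seed)
    n_agree = total = 0
    for k in range(n_pairs):
        alphabet = list("ACGTN") if k % 2 else list("ACGT")
        q = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 31)))
        r = "".join(rng.choice(alphabet, size=rng.integers(1, 31)))
        scheme = ALIGN_SCHEME if k % 3 else REALIGN_SCHEME
        total += 1
        if sw_score(q, r, scheme) == oracle_local_score(q, r, scheme):
            n_agree += 1
    return {"agreement_pct": 100.0 * n_agree / total, "n": total}


def charge_recovery_benchmark(seed: int, n_reads: int = 50_000) -> dict:
    """End-to-end charge recovery on an 8-transcript reference.

    Per-transcript measured charge must fall within 3 binomial standard
    errors of the generating charge; returns the passing fraction and the
    worst absolute error, plus the RPM normalisation check.
    """
    ref, _ = simulate_reference(n_families=4, members_per_family=2, seed=seed)
    charges = {tid: c for tid, c in zip(ref.ids(), CHARGE_LEVELS)}
    truth = uniform_truth(ref, charge=charges, seed=seed)
    reads, _ = simulate_reads(ref, truth, n_reads)
    processed, stats = preprocess_sample(reads, DEFAULT_ADAPTERS, "bench")
    annotations, _ = align_and_annotate(processed, ref)
    table = charge_table(annotations, "transcript").set_index("group")
    n_within = 0
    max_err = 0.0
    for tid, true_charge in charges.items():
        row = table.loc[tid]
        n = int(row.n_cca + row.n_cc)
        se_pp = 100.0 * np.sqrt(true_charge * (1 - true_charge) / n) if n else 0.0
        err = abs(float(row.charge_pct) - 100.0 * true_charge)
        max_err = max(max_err, err)
        if err <= 3 * se_pp or (se_pp == 0.0 and err == 0.0):
            n_within += 1
    rpm = rpm_table(annotations, "transcript")
    conserved = (
        stats["assigned"] + stats["ambiguous"] + stats["unmatched"] + stats["length_rejected"]
        == stats["input"]
    )
    return {
        "pct_within_3se": 100.0 * n_within / len(charges),
        "max_abs_error_pp": max_err,
        "rpm_sum": float(rpm.rpm.sum()),
        "reads_conserved": bool(conserved),
        "n_transcripts": len(charges),
        "n_reads": n_reads,
    }


def umi_qc_benchmark(seed: int, n_reads: int = 1000, n_replicates: int = 10_000) -> dict:
    """Occupancy expectation vs Monte-Carlo at the library's UMI space size."""
    k = umi_space_size(9, leading_purine=True)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_replicates)
    for i in range(n_replicates):
        sims[i] = np.unique(rng.integers(0, k, size=n_reads)).size
    mc = float(sims.mean())
    analytic = expected_unique_umis(n_reads, k)
    return {
        "umi_space": k,
        "analytic": analytic,
        "monte_carlo": mc,
        "rel_err_pct": 100.0 * abs(analytic - mc) / mc,
        "n": n_replicates,
    }


def titration_benchmark(seed: int, n_reps: int = 4) -> dict:
    """Correction-factor recovery: exact on noise-free data, bounded error at
    1 pp noise, and recovery of a planted +3 pp adapter bias."""
    f_levels = (0.5, 1.0, 2.0)
    tids = [f"t{k}" for k in range(len(f_levels))]
    f_true = dict(zip(tids, f_levels))
    t_a = {t: 85.0 for t in tids}
    t_b = {t: 6.0 for t in tids}

    clean, _ = simulate_titration(tids, f_true, t_a, t_b, n_reps=n_reps, noise_sd=0.0, seed=seed)
    clean_fit = TitrationModel().fit(clean)
    err_clean = max(abs(clean_fit.fits_[t].f - f_true[t]) for t in tids)

    noisy, _ = simulate_titration(tids, f_true, t_a, t_b, n_reps=n_reps, noise_sd=1.0, seed=seed + 1)
    noisy_fit = TitrationModel().fit(noisy)
    err_noisy = max(abs(noisy_fit.fits_[t].f - f_true[t]) for t in tids)

    biased, _ = simulate_titration(
        tids, f_true, t_a, t_b, n_reps=8, noise_sd=1.0,
        adapter_bias_pp={"I2Sp": 3.0}, seed=seed + 2,
    )
    report = TitrationModel().fit(biased).error_report("adapter").set_index("bin")
    return {
        "noise_free_max_abs_err": err_clean,
        "noisy_max_abs_err": err_noisy,
        "bias_bin_median_pp": float(report.loc["I2Sp", "median"]),
        "n_interior_ratios": 6,
        "n_reps": n_reps,
    }


def decay_benchmark(
    seed: int,
    n_groups_coverage: int = 50,
    n_boot: int = 1000,
) -> dict:
    """Decay-parameter recovery and bootstrap CI coverage.

    Noise-free recovery of (N0, t_half, N_inf); t_half relative error at 1 pp
    noise on the 11-timepoint x 4-replicate design; and the fraction of
    simulated groups whose bootstrap t_half CI covers the generating value.
    """
    clean, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=0.0, seed=seed)
    fit = DecayModel(n_boot=0).fit(clean).fits_["g"]
    clean_rel = max(
        abs(fit.n0 - 90.0) / 90.0, abs(fit.t_half - 120.0) / 120.0, abs(fit.n_inf - 2.0) / 2.0
    )

    noisy, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=1.0, seed=seed + 1)
    nfit = DecayModel(n_boot=0).fit(noisy).fits_["g"]
    thalf_rel_err = abs(nfit.t_half - 120.0) / 120.0

    rng = np.random.default_rng(seed + 2)
    truths = {
        f"g{i}": (float(rng.uniform(70, 95)), float(40.0 * 1.6 ** (i % 7)), float(rng.uniform(0.5, 3.0)))
        for i in range(n_groups_coverage)
    }
    series, _ = simulate_decay(truths, noise_sd=1.0, seed=seed + 3)
    model = DecayModel(n_boot=n_boot, seed=seed + 4).fit(series)
    covered = sum(
        1
        for gid, (_, th, _) in truths.items()
        if model.fits_[gid].ci95["t_half"][0] <= th <= model.fits_[gid].ci95["t_half"][1]
    )
    return {
        "noise_free_max_rel_err": clean_rel,
        "thalf_rel_err_noisy": thalf_rel_err,
        "bootstrap_coverage_pct": 100.0 * covered / n_groups_coverage,
        "n_groups": n_groups_coverage,
        "n_boot": n_boot,
    }


def build_hotspot_family(seed: int, n_reads: int = 1600):
    """Two-anticodon sister transcripts separable at a modified position and
    an unmodified diagnostic position (the masking rescue scenario)."""
    rng = np.random.default_rng(seed)
    body = list("".join(rng.choice(list("ACGT"), size=69)))
    diag, hot_pos = 50, 40
    seq_a, seq_b = list(body), list(body)
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
    truth = uniform_truth(ref, charge=0.7, seed=seed, seq_error=0.001)
    truth.hotspots = {tid: [Hotspot(position=hot_pos, mismatch_prob=0.55)] for tid in ref.ids()}
    reads, _ = simulate_reads(ref, truth, n_reads)
    processed, _ = preprocess_sample(reads, DEFAULT_ADAPTERS, "bench")
    return ref, processed


def masking_benchmark(seed: int, n_reads: int = 1600) -> dict:
    """Grid-search masking on the hotspot family: the optimal mask must cut
    multi-anticodon assignment without sacrificing mapped reads."""
    ref, processed = build_hotspot_family(seed, n_reads)
    grid = [
        MaskingParams(u, f, 0.9, it)
        for u in (False, True)
        for f in (0.2, 0.4)
        for it in (1, 2)
    ]
    base_multi, base_mapped = evaluate_mask(processed, ref, MaskSet())
    best, _ = grid_search(processed, ref, grid)
    return {
        "pct_multi_anticodon_unmasked": base_multi,
        "pct_multi_anticodon_masked": best.pct_multi_anticodon,
        "pct_mapped_unmasked": base_mapped,
        "pct_mapped_masked": best.pct_mapped,
        "mask_size": best.mask_size,
        "n_reads": n_reads,
    }
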