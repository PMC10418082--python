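# Methods

This note documents the models, conventions and numerical choices behind
`trnacharge`, and what the synthetic-data generator does and does not
emulate.

## Assay model

Charged tRNAs are sequenced with their full 3'-terminal CCA; uncharged tRNAs
are chemically truncated by one base and sequenced ending CC. A merged read
is laid out 5'→3' as `UMI (10 nt) + [5' non-template bases] + tRNA 3' portion
+ adapter barcode + splint-complementary context`. Reverse transcription
starts at the tRNA 3' end, so RT falloff truncates the transcript-5' side of
reads; modified nucleotides additionally cause mismatches, gaps and premature
stops.

## Preprocessing

- **Pair merging** is a built-in overlap merger: each mate's 3' adapter
  read-through is trimmed (suffix matching a prefix of the adapter, ≤ 10 %
  mismatches), read 2 is reverse-complemented, and the highest-scoring
  overlap of ≥ `min_overlap` (default 10) bases with ≤ 10 % mismatches
  collapses the pair. Consensus prefers the higher-quality base and read 1 on
  ties, preserving the 5' end. Merged reads shorter than `min_len` are
  rejected (default 25 nt, the blunt-end-ligation minimum; splint-assisted
  libraries use 39).
- **Barcode assignment** scans a bounded 3' window (last
  `len(barcode + splint context) + 4` bases) for a substring within Hamming
  distance 1 of each adapter's search sequence, taking the 3'-most hit.
  Two or more matching adapters → ambiguous; counted separately from
  no-match. Adapter tables are validated to pairwise barcode distance > 2 so
  distance-1 assignment cannot be ambiguous by design; unequal-length
  barcodes are compared over the 5' prefix of the longer. Indel-tolerant
  matching is deliberately not implemented (Hamming only).
- **UMI extraction** takes the first 10 bases verbatim; 5' non-template bases
  are left on the read for local alignment to soft-clip.
- **UMI QC** compares observed unique UMIs to the occupancy expectation
  E[X] = k(1 − ((k−1)/k)ⁿ) for n reads drawn uniformly from k = 2·4⁹
  possible UMIs. A variant with the roles of n and k exchanged is available
  (`literal_roles=True`); the two agree in the sparse regime n ≪ k but only
  the occupancy form tracks simulation when n approaches k, which is why it
  is the default.
- **Downsampling** (default cap 2·10⁶ reads) uses seeded reservoir sampling.

## Alignment

The reference is a few hundred transcripts, so heuristic seeding is pointless
risk: every read is scored against every transcript with an exhaustive
affine-gap Smith–Waterman (numba-compiled; a score-only O(n)-memory kernel
for the all-against-all pass and a full-matrix kernel for traceback of the
best hits). Plus strand only.

- **Scoring.** Primary scheme: match +1, mismatch −3, reference-N column 0
  for any query base, gap of length L costs 6 + 3·(L−1) (the opening penalty
  covers the first gapped base). Realignment scheme for profiling: +1 / −2,
  gap 3 + 2·(L−1). The e-value threshold of database-search tools is
  replaced by a raw score floor (`min_score`, default 20), which is
  deterministic and independent of database-size statistics.
- **Tie-breaking.** Traceback prefers diagonal over deletion over insertion;
  among equal-scoring end cells the 3'-most reference end, then the 3'-most
  query end, wins. This fixes misincorporation positions deterministically.
- **Annotation.** Up to three tied best transcripts are merged into one
  annotation. Uniqueness flags (transcript ⇒ anticodon ⇒ amino acid, nested)
  are computed over *all* tied transcripts even when more than three tie, so
  truncation to three can never fabricate uniqueness; such reads are flagged
  over-tied and excluded from transcript-level tables.
- **3'-end classification** is a reconstruction consistent with the assay
  design (the classification rule is not something the chemistry dictates
  uniquely): CCA requires the read's 3'-terminal base to align as a *match*
  to the transcript's final base with the last three columns all matches; CC
  requires the terminal base to match the penultimate C; anything else —
  2+ base truncation, terminal mismatch or gap, or 3' bases beyond the
  alignment — is `other`. Masked columns never qualify as matches, which is
  why the 3'-terminal three reference positions are never maskable.

## Quantification

Charge uses raw (uncorrected) counts — it is a ratio, so PCR duplication
cancels; RPM uses UMI-corrected counts (identical sequence + UMI counts
once). `other`-ended reads are excluded from charge but included in RPM:
they are real molecules, just uninformative about aminoacylation. Spike-in
transcripts get their own rows and are excluded from the cellular RPM
denominator (configurable). Groups under 100 informative reads are flagged
low-coverage, never dropped — filtering is a presentation decision.

## Misincorporation profiles

Unique-transcript reads are realigned to their unmasked transcript.
Conventions: a mismatch is attributed to its reference column; a deletion to
the 5'-most deleted reference base; an insertion to the reference index
immediately 3' of the inserted bases. Realignments spanning < 10 reference
positions are excluded (guards fractions against micro-alignments).
RT-stop percentage at position p is
`100 · (molecules whose 5'-most aligned index is exactly p+1) / max coverage`
— the denominator is the maximum (3'-side) coverage of the transcript. The
direction and normalisation are explicit choices: coverage is non-increasing
moving 3'→5' because cDNA synthesis starts at the 3' end.

## Reference masking

Mismatch frequencies are computed from UMI-corrected realignments and
filtered to ≥ 200 observations per transcript and ≥ 100 per position
(absent, not zero-filled, below threshold). Positions with frequency ≥
`min_mut_freq` (inclusive) are masked. Donation: for each ordered pair with
pairwise alignment score ≥ `frac_max_score` × min(self-scores) — normalising
by the smaller self-score keeps the ratio ≤ 1 under length asymmetry — each
donor masked position maps through the pairwise alignment and is copied iff
the nucleotides agree and the acceptor position has < 100 observations.
`unique_anno=False` realigns multi-annotation reads against each of their
tied transcripts. Iteration re-aligns against the current mask and rebuilds
from scratch each round; the grid search (defaults bracketing plausible
ranges: unique_anno ∈ {T, F}, min_mut_freq ∈ {0.05…0.20}, frac_max_score ∈
{0.85…1.00}, iteration ∈ {1, 2, 3}) minimises the multi-anticodon read
percentage, breaking ties toward the smaller mask and then stable grid
order, while reporting mapped percentage to expose any trade-off.

## Titration and decay models

Both fits are bound-constrained quasi-Newton (SciPy L-BFGS-B; a literal BFGS
has no bound support, so "BFGS with bounds" is realised as its
bound-constrained variant) with `ftol` 1e-9, 500 iterations max,
non-convergence flagged, and three starts (a data-driven start plus two
perturbations) against local minima.

- **Titration.** Endpoint ratios (100 and 0 % intact) define T_A and T_B as
  replicate means; the six interior ratios are fitted with pooled replicate
  residuals (not residuals of means). F bounds [0.25, 4]; estimates at a
  bound are flagged. The error report bins measured − predicted differences
  by any input column (adapter, ratio, replicate) over interior measurements.
- **Decay.** N(t) = N0·(½)^(t/t½) + N∞ with bounds N0 ∈ [0, 100],
  t½ ∈ [1, 10⁵] min, N∞ ∈ [0, 3.5]. The model value at t = 0 is N0 + N∞;
  since "charge at time zero" could mean either the amplitude or that sum,
  both are reported (`N0` and `charge_t0`). Initialisation: N0 from the
  first timepoint mean, N∞ from the last (clipped to bounds), t½ from the
  halfway crossing (fallback: geometric mean of positive times). The
  bootstrap draws one replicate value per timepoint independently (not
  case-resampling), refits from the point estimate (single start — the
  point estimate is an excellent basin anchor, and it keeps 1000 iterates
  fast), and takes 2.5/97.5 percentiles over the iterates.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the data-generating process end to end: transcript
families with tunable divergence, per-transcript true charge (binomial
CCA/CC at the read level), geometric RT falloff plus hotspot-specific
falloff, hotspot mismatches/gaps, uniform sequencing error, purine-led UMIs,
barcoded adapters, and optional exact-duplicate reads (PCR duplicates). The
model-level simulators (titration, decay) add Gaussian noise clipped to
[0, 100] — matching the residual structure the sum-of-squares fits assume —
whereas the read-level simulator produces genuinely binomial charge noise.

Not emulated: ligation-efficiency sequence bias, position-dependent quality
decay, chimeric reads, context-dependent RT error spectra, or interactions
between nearby modifications. Passing recovery tests therefore demonstrates
correctness of the computation under the stated noise model, not robustness
to every artefact of real libraries.

Default study sizes used by the recovery benchmarks: 50,000 reads over an
8-transcript reference (charges 0–0.95) for end-to-end charge recovery;
1,600 reads over the two-transcript hotspot family for masking; 6 interior
titration ratios × 4 replicates at 1 pp noise; 11 decay timepoints × 4
replicates, 50 groups × 1000 bootstrap iterates for CI coverage. These sizes
give binomial/Gaussian sampling errors comfortably inside the asserted
tolerances while keeping the full suite quick to run.

## Degenerate inputs and edge rules

- Sequences ending `CC` during CCA-repair are ambiguous; the full `CCA` is
  appended and a warning logged.
- Reads whose UMI space is saturated (n ≥ k) are handled by the occupancy
  expectation without special-casing.
- Zero mapped reads → empty RPM table with a warning; zero informative reads
  → charge undefined and flagged, never 0-filled.
- A constant decay series pins t½ at a bound and is flagged rather than
  erroring.
- Coordinates are 0-based half-open everywhere in the library; any 1-based
  presentation is confined to report boundaries and documented there.

## Known limitations

- Barcode matching is Hamming-only; an indel inside a barcode shifts the
  frame and the read is lost as unmatched rather than rescued.
- The masking grid search re-aligns the full read set per parameter
  combination; for large grids on large samples, subsample reads first (the
  objective is a percentage and converges quickly with read count).
- Intron handling is out of scope: the reference FASTA must contain mature,
  spliced sequences.
- The mask-donation similarity uses one optimal pairwise alignment; among
  co-optimal paths a different position mapping is conceivable (the
  deterministic tie-break makes the choice reproducible).
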