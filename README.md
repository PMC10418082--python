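# trnacharge

Analysis toolkit for **charge tRNA-Seq**: sequencing libraries that measure
tRNA aminoacylation ("charge") levels, relative tRNA expression, and
modification-induced misincorporation signatures in one assay.

## The problem and the method

Mature tRNAs end in an invariant 3'-terminal CCA; the amino acid esterifies to
the terminal A. Chemical treatment (periodate oxidation followed by
amine-induced β-elimination) removes the 3'-terminal base of *uncharged*
tRNAs, while the ester bond protects *charged* ones. Sequencing the 3' ends
therefore reads out charge directly: a molecule ending `...CCA` was
aminoacylated, one ending `...CC` was not. For a group *g* of molecules
(transcript, anticodon, or amino acid):

```
charge_g = 100 · n_CCA / (n_CCA + n_CC)        [percent]
```

Between the chemistry and that ratio sit several computational problems this
package solves:

- **Preprocessing** — read pairs are overlap-merged (5' end preserved),
  assigned to barcoded 3' adapters by a Hamming-distance-1 match over the
  barcode plus its splint-complementary context, and stripped of a 10-nt 5'
  UMI (purine + 9 random nt, 2·4⁹ = 524,288 possible sequences). A sample's
  observed unique UMIs are compared against the occupancy expectation
  E[X] = k·(1 − ((k−1)/k)ⁿ) as a quality check.
- **Guaranteed-best alignment** — every read is aligned to every reference
  transcript with an exhaustive affine-gap Smith–Waterman (match +1,
  mismatch −3, gap 6 + 3·(L−1), plus strand only). Score ties (up to three)
  are merged into one annotation; transcript-level reporting requires a
  unique transcript, codon-level a unique anticodon, amino-acid-level a
  unique amino acid.
- **Reference masking** — RT misincorporation at modified nucleotides makes
  reads mismatch their own transcript and tie with sister transcripts.
  High-mismatch positions are converted to `N` (scored 0), built iteratively
  under four tuning parameters (`unique_anno`, `min_mut_freq`,
  `frac_max_score`, `iteration`) with mask donation between highly similar
  transcripts, and tuned by a grid search minimising the percentage of reads
  assigned to transcripts with multiple anticodons.
- **Misincorporation profiles** — reads are realigned to their unmasked
  transcript (match +1, mismatch −2, gap −3/−2) to extract per-position
  mismatch fractions, gap fractions and RT-stop percentages (drop in
  UMI-corrected coverage moving 3'→5').
- **Titration model** — mixtures of intact (A) and deacylated (B) RNA at a
  percentage *p* of A deviate from the linear mixture because deacylation
  depletes some species. With transcript *i*'s concentration in B a factor
  *F<sub>i</sub>* of that in A, the predicted charge is
  `T_i(p) = (p·T_A + (100−p)·T_B·F_i) / (p + (100−p)·F_i)`; *F<sub>i</sub>*
  is fitted per transcript by bound-constrained least squares in [0.25, 4].
- **Decay model** — aminoacylation hydrolyses with first-order kinetics:
  `N(t) = N0·(1/2)^(t/t½) + N∞`, fitted with bounds N0 ∈ [0, 100] %,
  t½ ∈ [1, 10⁵] min, N∞ ∈ [0, 3.5] %, with 95 % bootstrap CIs (1000
  iterates, one replicate drawn per timepoint).

A synthetic-data generator (`trnacharge.simulate`) emulates the whole
data-generating process — reference families, per-transcript true charge,
modification hotspots, RT falloff, sequencing error, UMIs, adapter barcodes —
so every stage is testable against known truth without external data.

## Worked example

```python
from trnacharge.simulate import (simulate_reference, uniform_truth,
                                 simulate_reads, DEFAULT_ADAPTERS)
from trnacharge.preprocess import preprocess_sample
from trnacharge.align import align_and_annotate
from trnacharge.quant import charge_table

ref, _ = simulate_reference(n_families=4, members_per_family=2, seed=1)
charges = dict(zip(ref.ids(), [0, 0.25, 0.5, 0.75, 0.95, 0.3, 0.6, 0.9]))
truth = uniform_truth(ref, charge=charges, seed=1)
reads, _ = simulate_reads(ref, truth, 4000)
processed, stats = preprocess_sample(reads, DEFAULT_ADAPTERS, "s1")
annotations, _ = align_and_annotate(processed, ref)
print(charge_table(annotations, "transcript"))
```

prints (charge in percent; `n_cca`/`n_cc` are raw read tallies):

```
              group  n_cca  n_cc  charge_pct  low_coverage
0  tRNA-Ala-AGC-2-1    229   247   48.109244         False
1  tRNA-Ala-AGC-2-2    365   116   75.883576         False
2  tRNA-Lys-TTT-1-1      0   519    0.000000         False
3  tRNA-Lys-TTT-1-2    112   363   23.578947         False
4  tRNA-Met-CAT-3-1    458    26   94.628099         False
5  tRNA-Met-CAT-3-2    148   368   28.682171         False
6  tRNA-Phe-GAA-4-1    304   180   62.809917         False
7  tRNA-Phe-GAA-4-2    425    57   88.174274         False
```

Each measured charge sits within binomial sampling error of the generating
value (e.g. 48.1 % measured at ~500 informative reads for a true charge of
50 %). The same objects feed `rpm_table` (UMI-corrected reads per million),
`modprofile` (misincorporation profiles) and `maskopt` (mask optimisation).

The `trnacharge` command exposes the same stages as subcommands:
`simulate`, `preprocess`, `align`, `quantify`, `profile`, `mask-optimize`,
`titrate`, `decay`, and `run` for the end-to-end pipeline.

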