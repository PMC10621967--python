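# Methods

haplocn phases germline heterozygous SNPs into long-range haplotypes by
borrowing allelic-imbalance signal across the bulk samples of one
tumour, then re-estimates haplotype-specific copy numbers and
classifies somatic copy-number alterations (SCNAs) by clonality. This
note describes the model, its assumptions, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was open.

## Model and assumptions

For each tumour sample `j` with purity `ρ_j` (fraction of cancer
cells) and ploidy `ψ_t,j` (width-weighted mean total copy number), a
genomic region with haplotype copy numbers `(n_A, n_B)` produces, at a
heterozygous SNP whose B allele lies on haplotype B,

```
E[BAF]  = (n_B ρ + (1 − ρ)) / ((n_A + n_B) ρ + 2 (1 − ρ))
E[LogR] = log2[(2 (1 − ρ) + ρ (n_A + n_B)) / (2 (1 − ρ) + ρ ψ_t)]
```

with `1 − E[BAF]` for a B allele on haplotype A. The package assumes
the input purities, ploidies and segmentations from the upstream
single-sample caller (ASCAT/Sequenza-shaped tables) are correct; it
does not re-estimate purity and does not model within-sample subclonal
mixtures — each sample is summarised by its dominant copy-number
state per region.

The pipeline has five stages:

1. **Minimum consistent segmentation (MCS).** The union of all
   per-sample segment breakpoints, with samples of origin tracked.
   Adjacent breakpoints closer than `max_gap` (default 100 kbp) are
   merged left-to-right, but only when their origin sets are disjoint:
   jitter of the same boundary estimated in different samples is
   collapsed, while focal structure within one sample is preserved.
   Merging cascades; the merged breakpoint keeps the leftmost position.
   Bins between consecutive breakpoints are kept only if an input
   segment of every sample covers the bin midpoint (with exact
   breakpoints a bin is entirely inside or outside a segment, so the
   midpoint rule is robust to sub-`max_gap` edge jitter).
2. **Reference phasing.** Per bin, candidate references are samples
   whose input major copy number differs from half the total. The
   candidate with the largest mirrored BAF — mean `|b − 0.5|`
   directly when a bin has fewer than `min_snps = 3` het SNPs or BAF
   variance below `1e−5`, otherwise half the separation of a
   two-component equal-variance Gaussian mixture — becomes the
   reference. SNPs with BAF strictly above the reference's bin mean
   are assigned to haplotype B; the assignment is shared by all
   samples, which is valid because germline phase is constant within a
   patient. Bins with no input-imbalanced sample stay unphased.
3. **Imbalance testing and copy-number re-estimation.** Each (bin,
   sample) is tested with a two-sided Wilcoxon rank-sum test between
   the two haplotypes' BAF values; raw p-values are Holm-adjusted
   across all tests of the patient (5% family-wise error rate) and
   gated on Cohen's d (pooled, Bessel-corrected SD) with
   `d_min = 1.0`. By default copy numbers are re-estimated (inverting
   the forward model above) only where imbalance is newly detected
   relative to the input states; carried-forward input states are
   oriented onto haplotypes by the consolidated haplotype-B BAF (B-SNP
   values pooled with mirrored A-SNP values). Re-estimation can also
   be forced everywhere or disabled. A nonparametric alternative
   classifies a bin into an integer state with Gaussian naive Bayes
   trained on the (haplotype BAF, LogR) features of the sample's other
   bins and the same bin in other samples. Sample ploidy is then
   recomputed once as the width-weighted mean of the fractional totals
   (no fixed-point iteration).
4. **Horizontal phasing.** Within a chromosome the A/B assignment of
   neighbouring bins is made consistent by choosing per-bin flips
   (exchanging `n_A`/`n_B` in all samples) that minimise the summed
   Hamming distance between neighbouring integer states over samples
   and haplotypes. The total decomposes over boundaries and each
   boundary's relative orientation is free, so per-boundary greedy
   minimisation is globally optimal (verified exhaustively in tests);
   ties walk back to earlier bins and default to unflipped at the
   chromosome start. Unphased bins are bridged. Finally each
   chromosome's labels are swapped if needed so haplotype A has the
   larger width-weighted mean copy number; labels remain arbitrary
   *between* chromosomes.
5. **Event calling and clonality.** Amplifications, gains and losses
   are called per sample against purity-ploidy LogR cutoffs (mixture
   factors 2, 1.25, 0.75 relative to ploidy; a diploid reference and a
   one-tailed within-bin t-test variant are available). LOH requires
   one haplotype at 0 copies; copy-neutral LOH additionally requires
   the major allele to equal the rounded sample ploidy; homozygous
   deletion requires both at 0. An event class is clonal when present
   in every sample on the same major haplotype; present-in-all events
   whose major haplotype is mirrored between samples (MSAI) are
   reassigned subclonal and parallel; for partially present events,
   parallelism is judged among the harbouring samples only.
   Genome-fraction metrics weight bins by width over the total MCS
   width, optionally within user-defined sample subgroups (which reuse
   the patient-wide phasing).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap` | 100 000 bp | breakpoint merge distance in the MCS |
| `alpha` | 0.05 | family-wise error rate for imbalance tests |
| `d_min` | 1.0 | minimum \|Cohen's d\| for an imbalance call |
| `min_snps` | 3 | below this, mirrored BAF is computed directly |
| `min_baf_var` | 1e−5 | below this, mirrored BAF is computed directly |
| `policy` | `on_new_imbalance` | when to re-estimate copy numbers |
| `model` | `parametric` | forward-model inversion vs naive Bayes |
| `mode` | `mean` | mean-LogR vs t-test dosage calling |
| `reference` | `ploidy` | cutoffs relative to ploidy vs diploid |

`d_min = 1.0` couples the imbalance call to effect size rather than
sample size: at 200× coverage the per-SNP binomial SD near BAF 0.5 is
≈ 0.035, so d = 1 corresponds to a haplotype BAF separation of
≈ 3.5%, which places the detection limit for a 2|0 copy-neutral LOH
at a cancer cell fraction of ~4–5% (the separation equals the CCF).

## The synthetic-data generator

`simulate_patient` draws a patient from known haplotype-specific
truth: ~6 chromosomes of 2–4 megabase-scale segments, 60–120 het SNPs
per segment, per-sample purities uniform in 0.3–0.9, BAF =
Binomial(coverage, E[BAF])/coverage at 100× and LogR = E[LogR] +
N(0, 0.15). Each patient contains one event-free chromosome (to
measure spurious calls), one chromosome with whole-chromosome gains of
opposite haplotypes in two samples (planted MSAI), and backbone
whole-chromosome events plus at most one segmental event per sample
and chromosome elsewhere. Input segmentations are emitted in
major/minor configuration with equal-configuration neighbours merged,
optionally jittered.

Two deliberate restrictions keep the planted truth identifiable, and
bound what passing tests show: segmental losses never stack into
homozygous deletions (which would sever the allelic-imbalance
continuity that makes within-chromosome phase identifiable), and every
event chromosome carries a whole-chromosome event in some sample.
Real tumours contain focal homozygous deletions, regions where no
sample is imbalanced (inherently unphaseable), GC-wave and replication
artefacts in LogR, segmentation errors beyond breakpoint jitter, and
incorrect purity/ploidy inputs — none of which the generator
emulates. Recovery results on synthetic data are therefore statements
about the algorithm under its own model, not about caller robustness
on real sequencing data.

The copy-neutral LOH sweep simulates 125 candidate segments of
200–2000 het SNPs (a desk-scale stand-in for cohort-derived segments
of at least one fifth of a chromosome): a reference sample with
`ρ·|n_A − n_B| ≥ 0.5` provides the phasing, and the test sample
carries a 2|0 state at each CCF of a 1–30% grid with BAF drawn at
200× coverage. Detection is the package's imbalance test at defaults
(raw p here — each simulated event is its own family). An unphased
baseline detector (BIC selection between one- and two-component BAF
mixtures, capped at 300 SNPs) mimics what a single sample's BAF alone
supports; its limit sits around 10–11% CCF versus 4–5% for
reference phasing.

The MSAI permutation null replays per-branch copy-number events
(chromosomal/segmental gains and losses, whole-genome doubling) onto a
sample tree, then re-simulates each dataset with event locations
redrawn uniformly (chromosome uniform; segmental start uniform with
length fixed; haplotype uniform). The right-tailed p-value uses the
add-one estimator `(1 + #{null ≥ observed}) / (n_sims + 1)`; on data
generated from the null itself these p-values are uniform. For
cross-patient summaries a Benjamini–Hochberg helper is provided,
labelled as such.

Artificial normal samples (binomial BAF around 0.5, Gaussian LogR
around 0, balanced 1/1 segments spanning the tumour samples' covered
extent) provide a specificity control when appended to a patient.

## Numerical choices and degenerate inputs

- Integerisation clamps negative fractional copy numbers to 0, then
  rounds half up.
- Zero pooled SD in Cohen's d gives d = 0 for equal means and ±inf
  otherwise; bins with an empty haplotype or fewer than three SNPs in
  total are untestable and never flagged.
- The Gaussian mixture uses 10 seeded restarts with tied variances;
  non-convergence falls back to the direct mirrored mean, flagged.
  Fitted to a single balanced band, the two-component mixture keeps a
  small positive half-separation (~0.6× the per-SNP noise SD) — one
  reason reference candidates are restricted to input-imbalanced
  samples.
- The naive-Bayes model uses a generous variance floor
  (`var_smoothing = 1e-2`): class variances estimated from a handful
  of bins otherwise collapse and make a query an outlier of its own
  class. Fewer than two distinct training classes falls back to the
  parametric model, flagged.
- Reference ties go to the sample with more SNPs in the bin, then the
  lexicographically smallest sample id. SNPs with BAF exactly at the
  reference segment mean go to haplotype A (strict `>`).
- A homozygous deletion at purity 1 has zero expected depth; its
  expected BAF is defined as 0.5 and flagged.
- SNPs missing (position or value) in any sample are dropped
  patient-wide to keep cross-sample comparability; counts are logged.

## Known limitations

- One reference sample per bin: other imbalanced samples' phasing
  information is unused.
- Phase is unidentifiable across regions where no sample is
  imbalanced, and between chromosomes; comparisons against truth must
  allow a global per-chromosome label swap.
- Ploidy is updated once, not iterated to convergence, and purity is
  trusted as given.
- Parallel events arising on the *same* haplotype are invisible to
  mirroring-based detection.
- Genome fractions are relative to the MCS width, so patients with
  poor shared coverage are summarised over less genome.
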