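# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations. All internal coordinates are 0-based half-open; GTF
(1-based inclusive) is converted exactly once at the I/O boundary.

## Transcript classification

A query transcript is compared with every reference transcript on its
scaffold and receives one code with precedence `=`, `o`, `i`, `y`, `p`,
`u`:

* `=` identical exon chain (same coordinates, compatible strand);
* `o` any query exon overlaps any reference exon — checked on either
  strand, so exonic overlap always disqualifies a candidate regardless of
  orientation;
* `i` the query lies entirely within a single reference intron;
* `y` a full reference transcript lies within a query intron;
* `p` no overlap, and the query begins within 2,000 bp downstream of a
  reference 3′ end, where "downstream" follows the reference strand;
* `u` everything else (intergenic).

The precedence order is a design choice: the published tools do not fix
one, and putting `o` ahead of the containment codes matches the intent of
keeping only candidates from non-coding loci. Codes `i` and `y` are
strand-agnostic by default (a `stranded_containment` switch restricts them
to same-strand references); unstranded queries match either strand
throughout. The candidate filter keeps codes i/y/p/u with **spliced**
length ≥ 200 nt, inclusive — genomic span is never used.

Group characterization (length, exon count, GC content with N excluded
from numerator and denominator, expression on the log10(TPM+1) scale) uses
a two-sided Mann–Whitney U test: exact enumeration over all
C(n1+n2, n1) assignments (tie-aware) when both groups have ≤ 8
observations, otherwise the normal approximation with tie and continuity
corrections.

## Coding potential

Four features per transcript: longest-ORF length (nt), ORF coverage,
Fickett TESTCODE, and hexamer usage bias. ORFs are ATG→stop on the sense
strand in three frames (assembled transcripts are strand-resolved); every
ATG opens its own ORF, stops are included, and ORFs without a stop run to
the frame end. The Fickett tables are the published TESTCODE position and
content lookup tables, shipped as a JSON data file whose SHA-256 is
verified at import. Hexamer bias is the mean log-ratio of in-frame (step-3)
hexamer frequencies in training ORFs versus step-1 hexamer frequencies in
noncoding sequence, with additive smoothing (pseudocount 1).

The logistic model is fit by IRLS on internally standardized features
(convergence when the largest coefficient change is below 1e-8, at most
100 iterations), with coefficients reported on the original scale. If the
fit fails to converge or coefficients explode — the perfect-separation
regime, which synthetic data regularly produces — the model is refit with
an L2 penalty of 1e-4 on the standardized coefficients and flagged.

The probability cutoff is calibrated by evaluating every observed score as
a threshold ("coding iff probability ≥ t"), choosing the accuracy maximum
(ties to the smallest threshold) and reporting the ROC and trapezoidal
AUC. In the pipeline the benchmark is the reference annotation itself
(known mRNAs vs known lncRNAs), mirroring a curated-set calibration; a
fixed cutoff can be supplied instead. Candidates scoring below the cutoff
are still discarded when they contain a complete ORF of ≥ 100 codons
(inclusive; the stop codon counts toward the 100, i.e. ≥ 300 nt) or appear
in a precomputed homology table (transcript_id, hit_id, evalue). Homology
search itself is out of scope — the filter consumes its results, which
keeps the pipeline free of external databases.

## Differential expression

The test is a deliberately simple negative-binomial Wald pipeline rather
than a full DESeq2 re-implementation; its contract is operating
characteristics, not numeric equality with any specific tool.

* **Prefilter:** keep a gene iff it has nonzero counts in ≥ 3 samples of
  at least one group. The source description of this rule is grammatically
  ambiguous; this reading ("expressed in at least one condition") is the
  documented choice.
* **Size factors:** median-of-ratios over genes expressed in all samples.
* **Dispersion:** per-gene method-of-moments on normalized counts within
  groups, α = max((s²−μ)/μ², 1e-8), pooled across groups by degrees of
  freedom, then shrunk 50/50 on the log scale toward a least-squares trend
  of log α on log μ. The floor, the equal-weight shrinkage, and the
  log-linear trend are pragmatic defaults; with 16 samples per group the
  Wald test's null calibration is conservative under them (measured null
  call rate at FDR < 0.01 is well below 1%).
* **Wald test:** with a two-group design and size-factor offsets the NB
  log-link GLM factorizes per group, so the IRLS update is a scalar Newton
  step on each group's log-mean, vectorized across all genes
  (score Σ(y−μ)/(1+αμ), information Σμ/(1+αμ)). log2FC is the group
  contrast divided by ln 2; the Wald p is two-sided normal. Non-converged
  genes (100 iterations) get NA p-values and a flag.
* **Calls:** up_in_mated iff log2FC ≥ 1 and FDR < 0.01; up_in_virgin
  symmetric. The fold-change bound is inclusive, the FDR bound strict. BH adjustment uses the step-up procedure
  with cumulative-minimum monotonization; NA p-values propagate.
* **Clustering:** technical runs are averaged per biological replicate
  (they are correlated pseudo-replicates for this purpose, though the test
  above uses all 16 libraries per group as samples);
  genes are z-scored with the population SD (zero-variance rows become
  zero vectors and are flagged); both axes use average-linkage
  agglomerative clustering on Euclidean distance with input-order
  tie-breaking.

Effective length for TPM is the spliced transcript length (no
fragment-length correction). All-zero samples yield all-zero TPM columns.

## Co-regulation network

Spearman's ρ is the Pearson correlation of average ranks; exactly equal or
exactly reversed rank vectors return ±1 with p = 0, zero-variance input
returns NA. The p-value uses the t approximation with n−2 df (the n = 16
regime); an exact permutation p is available for n ≤ 8. All DEL×DEG pairs
are tested within each condition's 16 libraries separately; an edge needs
|ρ| > 0.8 and p < 0.01, both strict, on raw p-values — a deliberately
liberal default; a BH flag exists. A flag can switch to
biological-replicate averaging (8 samples per condition) instead of all
libraries.

## Triplex search

Matching follows Hoogsteen triplet rules per motif (pyrimidine U·A/C·G,
parallel; purine A·A/G·G, antiparallel; mixed U·A/G·G, both orientations),
with both DNA strands considered as candidate purine strands and TTS
coordinates always reported on the given strand. A reported match is a
*maximal* ungapped window — extending it one base in either direction
violates a constraint — satisfying all of: length ≥ 15 nt (the published
length parameter read as a minimum; a maximum reading would exclude nearly
all reported triplexes), error rate strictly < 0.20 (so a 15-mer admits at
most 2 errors), at most 3 consecutive errors ("constitutive" read as
consecutive), and guanine fraction of the TTS purine strand ≥ 0.20
(inclusive). N never matches and counts as non-G/non-A. The scanner walks
alignment diagonals with prefix sums and a jump table of fatal error runs
(4 consecutive errors bound every window crossing them), which keeps locus
scans near-linear; the test suite holds it to exact set equality with a
brute-force window enumerator. TTS clustering merges overlapping or
gap-adjacent sites per scaffold (both purine strands pooled, since a TTS
names a duplex region), reports member counts, interval width and
GA-fraction, and flags clusters with ≥ 10 members as high-frequency —
member count and width are both exposed rather than guessing which one a
"position count" means.

## Synthetic data

The generator emulates the downstream products of a 32-library study
(2 conditions × 4 biological replicates × 4 technical runs), not the reads:

* **Genome/annotation:** scaffolds of i.i.d. background sequence (slightly
  AT-rich, A/C/G/T = 0.30/0.20/0.20/0.30); 130 multi-exon mRNAs whose
  spliced sequence carries a codon-biased ORF of 100–220 codons (codon
  usage drawn once from a Dirichlet and mixed with uniform by the
  `hexamer_bias_strength` knob, 0.8 by default — the composition gap that
  makes coding potential learnable); 70 reference lncRNAs with 2–3 exons
  and background composition. The panel is deliberately large enough
  (~200 genes) that no single induced gene dominates library totals, which
  keeps TPM self-normalization from distorting planted correlations — a
  small-panel artifact real transcriptomes do not have.
* **Novel plants:** class-i/p/u novels and decoys are single-exon (the
  shape newly assembled lncRNAs typically take); class-y novels have two exons
  because the code requires an intron enclosing a full reference. Decoys
  overlap reference exons and must never survive classification.
* **Counts:** gene means log-uniform on (20, 500), NB dispersions uniform
  on (0.05, 0.3), per-library log-normal size factors (sd 0.1). Technical
  runs share their biological replicate's Gamma latent and differ only by
  size factor and Poisson noise. Fold-changes are planted on 6 mRNAs
  (±1.5–3) and 4 lncRNAs (±2–3), echoing strong mating-induced shifts.
* **Correlated pairs:** planted DEL:DEG pairs are drawn through a Gaussian
  copula on the NB marginals within the target condition (independent
  elsewhere). The stored `copula_rho` is the *target Spearman*; the
  Gaussian correlation used is 2·sin(πρ/6), the exact inverse of the
  copula's Spearman, so the target is achieved in expectation. Pair genes
  draw their means from the upper expression range (150–500): focal
  co-regulated genes are typically highly expressed, and low-count
  discreteness would otherwise erode rank correlations through ties. Pair genes are i.i.d.
  per library (no shared technical latent); the copula, not the replicate
  structure, carries their dependence.
* **Triplex plant:** a GA tract (30 nt, G share 0.5, purity 1.0 by
  default) is written into the first intron of the mRNA that is
  copula-paired with the carrier lncRNA, and the parallel pyrimidine-motif
  complement (A→U, G→C) into the carrier's largest exon, so the
  co-expression network points the triplex scan at the right locus.
  Purity < 1 degrades tract positions to pyrimidines and defeats the
  search at 0.5, as intended.

Determinism: one seed feeds a `SeedSequence` forked into independent
streams per stage (genome, novels, counts, triplex), so identical
configurations reproduce byte-identical outputs and stages can be re-run
in isolation.

What passing tests on this generator do **not** show: robustness to
alignment and assembly artifacts, fragment-length and GC bias in
quantification, outlier samples, batch structure beyond library size,
multi-isoform genes, or the fragmented-scaffold problems of a real draft
genome. The generator's single-transcript genes also make
transcript-level and gene-level analysis coincide.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the measured properties are stable:
oracle equivalences on 1,000 random transcripts/sequences and 500 random
200-nt sequence pairs (5 seeds × 100); DE operating characteristics on
2,000 genes × 32 samples over 10 seeds; network retention over 10 full
study simulations and 50 null runs; the end-to-end pipeline at the default
~200-gene genome.

## Known limitations

* The dispersion estimator is moment-based with fixed 50/50 trend
  shrinkage — adequate at n = 16/group (conservative null), but it is not
  a Cox–Reid MLE and will be biased at small n.
* Edge p-values are raw by design; with many DELs × DEGs the network's
  family-wise error is uncontrolled (the optional BH flag addresses this).
* The triplex scorer is purely combinatorial (length − errors); no
  thermodynamics, and no attempt to reproduce any specific tool's q-gram
  heuristics or tie-breaking.
* The coding-potential cutoff calibrated on the synthetic benchmark is
  usually degenerate (perfect separation); on real data the published
  cutoffs in the 0.2–0.25 range are the sensible override.
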