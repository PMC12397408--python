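# Methods

This note documents the models and procedures implemented in `beadsplice`,
the parameter defaults and why they were chosen, what the simulators do and
do not emulate, and the numerical conventions that make results
reproducible.

## Molecule layout

A barcoded cDNA molecule is, 5'→3' on the barcode strand:

```
primer | barcode part 1 (8 bp) | linker | barcode part 2 (6 bp) | UMI (9 bp) | polyT (30 bp) | cDNA
```

One `MoleculeLayout` object is shared by the simulator and the caller, so
benchmarks are self-consistent by construction. Defaults: the UPS
amplification primer `AAGCAGTGGTATCAACGCAGAGT`; linker
`TCTTCAGCGTTCCCGAGA` (slide vendors do not publish the linker, so this
Slide-seq-lineage sequence is a documented, fully configurable convention);
barcode split 8+6 summing to the 14 bp whitelist barcode length; 9 bp UMIs
whose last two bases are never T (the space therefore holds
4⁷·3² = 147,456 distinct UMIs — the non-T constraint prevents the UMI tail
from being absorbed into the poly(T) run); 30 bp poly(T). The cDNA is the
reverse complement of the transcript, as produced by poly(A)-primed reverse
transcription.

## Barcode calling

Per read, in order:

1. **poly(T)**: leftmost sliding window (length 16) with T-fraction ≥ 0.8,
   trimmed to T at its edges, extended maximally through adjacent Ts, and
   required to contain ≥ 12 T. The window parameters are this package's
   choice: 16·0.8 ≈ 13 matching bases tolerates the expected ~4.4% error
   rate inside a 30 bp tail while rejecting random sequence (a random
   window reaches 13/16 T with probability ~10⁻⁵).
2. **primer, linker**: searched in the region preceding the poly(T) start
   (construct length + 20 bp slack). Each must share ≥ 1 exact k-mer with
   the region (k=6 primer, k=5 linker — the index shrinks the search and
   skips hopeless reads cheaply) and reach a local-alignment score of
   length − 4 (+1/−1/−1 scoring), i.e. up to two substitutions or four
   indels/clipped bases.
3. **barcode**: the candidate sequence is the concatenation of
   (primer end → linker start) and the 6 bases after the linker end.
   Whitelist candidates sharing ≥ 1 exact 6-mer with it are scored by
   Smith–Waterman; the best candidate is called iff its score reaches
   `min_score` (default 13 of 14) *and* it is the unique top scorer —
   a tied top score is reported as no call, protecting precision.
4. **UMI**: the read subsequence between the nominal barcode end and the
   poly(T) start, recorded verbatim (its length may deviate from 9 under
   indels; error tolerance is deferred to deduplication).
5. If any component is missing, all steps are retried on the reverse
   complement. Reads with no call are excluded downstream.

The failure label of an uncalled read is the first failing criterion of the
*forward* attempt (`no_polyT`, `no_primer`, `no_linker`, `low_score`):
the reverse complement of, say, a poly(A)-only read trivially "contains"
poly(T), so labeling by the furthest-progressing attempt would misattribute
such failures.

Alignment is implemented twice on purpose: a full-DP reference
(`local_align`, with deterministic tie-breaks — lowest target start, then
lowest query start, then lowest ends) and numba kernels used for batch
calling; tests assert their equality against an independent textbook DP on
random sequences. An exact-match shortcut skips alignment when the
extracted candidate is itself a whitelist member (no other barcode can tie
a full-length exact match inside a 14 bp window).

## UMI deduplication

Reads are grouped by (assigned gene, barcode). Within a group a single
greedy pass (input order by default; an optional pre-sort by splice count
is available, since any greedy pass is order-dependent) maintains
representative UMIs: a read joins the closest representative within edit
distance ≤ 2, with the first-collected representative winning ties;
otherwise its UMI becomes a new representative. Per cluster the read
covering the most splice junctions is kept (tie: lexicographically
smallest read id).

The distance is Levenshtein with free end gaps, modelling UMI boundary
slippage on noisy reads. Fully free end gaps would be degenerate — any two
strings can slide past each other at cost 0 — so free end-gap length is
capped at the clustering threshold (2 bases per end). With ~147K possible
UMIs and a handful of molecules per (gene, barcode) group, accidental
merges of distinct molecules are rare; tests verify molecule-count recovery
within 2% under simulated PCR duplication.

## Cassette-exon tests

Candidate exons are the distinct internal exon blocks (flanked by introns
in at least one read) of each gene — the minimal universe derivable from
reads alone; an annotation-derived list can be unioned in. Only spliced
reads are used, optionally restricted to reads whose introns all match the
splice-site consensus (consensus flags are an upstream input). For an exon
[s, e], every gene-assigned overlapping read increments exactly one of:

* **A** — contains the exon block with introns ending at s−1 and starting
  at e+1;
* **B** — an intron ends at s−1 and the read's right end lies in [s, e];
* **C** — an intron starts at e+1 and the read's left end lies in [s, e];
* **D** — an intron spans the exon;
* **E** — any other overlap.

"Left"/"right" are genomic directions; strand is carried for reporting.
Boundary convention: read ends *at* the exon boundary count as "on the
exon" (B/C boundary-inclusive). PSI = (A+B+C)/(A+B+C+D),
leftPSI = (A+B)/(A+B+D), rightPSI = (A+C)/(A+C+D).

Filters on the pooled two-group counts: A+B+C+D ≥ 10 (minimum evidence);
(A+B+C+D)/(A+B+C+D+E) ≥ 0.8 (the binary inclusion/exclusion view must
describe ≥ 80% of overlapping reads); leftPSI and rightPSI ∈ [0.05, 0.95]
(both splice sites genuinely alternative). Groups are compared by a
two-sided Fisher exact test on [[incl₁, excl₁], [incl₂, excl₂]] with
incl = A+B+C and excl = D, tested only when both groups have ≥ 10
informative reads and ≥ 3 of 4 cells have expected counts ≥ 5. P-values
are Benjamini–Yekutieli corrected (valid under arbitrary dependence of
overlapping exon tests); an exon is significant at FDR < 0.05 and
|ΔPSI| ≥ 0.2 (both parameterized).

## Usage tests (poly(A), TSS, acceptor/donor, isoform)

Per gene, feature categories (poly(A) coordinate; TSS; per-intron
acceptor/donor positions, strand-aware, one count per intron; or the full
(TSS, intron chain, poly(A)) triple — requiring all three parts, so reads
lacking a TSS do not contribute isoform counts) are ranked by pooled
abundance (ID 1 = most abundant; ties by identifier string) and collapsed
to the top 10 plus an "other" row (K ≤ 11). Genes with fewer than 10 reads
are not tested. The 2×K table is tested with Pearson's chi-squared (no
continuity correction, no expected-count gating — a warning is emitted
when > 20% of expected counts fall below 5) and BH-corrected.

ΔΠ is the sum of the two largest positive per-category changes in usage
fraction (group 2 − group 1); it is 0 iff the usage vectors are identical,
non-negative by construction, and bounded by 1. The phrase "change from the
top two" admits other readings; this one was chosen because it is
non-negative by definition and bounded, matching how the effect size is
used. Last-exon length is the strand-wise final exon block of a
poly(A)-bearing read (end − start + 1, 1-based inclusive), averaged per
(gene, group); gene sets can be stratified by |ΔΠ| (e.g. < 0.2 vs > 0.2).

## Power-equalized downsampling

Two contrasts with different depths cannot be compared by raw
percent-significant. The procedure: keep exons with, per group, ≥ 17 reads
contributed by ≥ 3 distinct samples (group-total reading; the stricter
per-sample reading — ≥ N reads in each of ≥ 3 samples — is available and is
the default in the cell-type-restricted preset: ≥ 7 reads/sample, 15 reads
drawn, 30 exons); per iteration draw ≤ 1 exon per gene, 50 exons, exactly
20 reads per exon and group without replacement (optionally capped per
individual at ⌈reads/min_samples⌉ so no single or pair of individuals
dominates); Fisher-test the 50 equal-column-sum 2×2 tables; correct within
the fixed family (BY, matching the exon tests); record percent significant.
100 iterations per contrast yield distributions compared by a two-sided
Wilcoxon rank-sum test. Iterations consume independent child seeds of one
seed sequence: runs are exactly reproducible and contrasts are independent.

## Read simulator

Molecules are assembled from the layout with barcodes drawn uniformly from
the whitelist (default 70,000 random distinct 14-mers), constrained random
UMIs, and transcripts drawn from a synthetic pool (default 500 random
sequences, log-normal lengths with median ≈ 490 bases clipped to
[150, 4000], log-normal expression weights) or a user FASTA. Reads are
optionally PCR-duplicated (same barcode/UMI/transcript, independent
errors), truncated (probability 0.35 of removing a geometric,
mean-300-base prefix from the barcode-proximal end — chosen so that most
truncations delete the barcode region, reproducing the qualitative
poly(T)/linker loss pattern of real ONT libraries), strand-flipped with
probability 0.5, and error-injected i.i.d. per base at 1.4% substitution /
2.0% insertion / 1.0% deletion (substituted bases always differ; an
insertion is placed after the base it is drawn for). A truth table records
barcode, UMI, transcript, truncation, strand, and whether the barcode
region survived.

Scoring: a correct call is a true positive, a wrong call a false positive,
no call a false negative; precision = TP/(TP+FP),
recall = TP/(TP+FP+FN) = TP/total, since every simulated read carries a
true barcode. Calls made once at min score 11 are re-thresholded at
11/12/13/14, which is exact because the winning candidate does not depend
on the threshold.

### What the simulator does and does not emulate

It emulates the molecule structure, whitelist scale, aggregate error rates,
truncation, strand ambiguity and PCR duplication. It does **not** emulate a
trained sequencing-error *profile*: real ONT errors cluster (homopolymer
indels, burst errors), whereas this model is i.i.d. at the stated aggregate
rates. The consequences are predictable and visible in the benchmark: under
i.i.d. errors the probability that a 14 bp barcode region is error-free —
a hard ceiling for a perfect score-14 call — is
(1−0.024)¹⁴·(1−0.02)¹³ ≈ 0.55, so recall at high score cutoffs sits
substantially below what a clustered error process yields on the same
aggregate rates (which produces more fully clean barcode regions, and,
symmetrically, more multi-error reads that depress precision at low
cutoffs). Desk-scale benchmark numbers from `scripts/acceptance.py` should
be read with this approximation in mind; the monotone precision/recall
trade-off and the truncation-driven recall loss are robust to it. The
synthetic AllInfo-level generators (cassette and poly(A)-usage read models)
likewise use idealized binomial/multinomial sampling with unique UMIs;
passing calibration tests on them demonstrates correctness of the testing
machinery, not performance on real tissue data.

## Numerical and engineering conventions

* Genomic coordinates are 1-based inclusive; exon ids serialize as
  `chrom_start_end_strand`. Read-coordinate spans (alignment components)
  are 0-based half-open on the oriented read.
* AllInfo dialect v1: 11 tab-separated columns (read id, gene, group,
  barcode, UMI, intron chain, TSS, poly(A), exon chain, novelty, intron
  count); chains serialize `chrom:strand:start-end;start-end;…`; absent
  TSS/poly(A) is `"."` (absence is first-class — only a minority of reads
  carry a TSS). Malformed rows are counted and skipped with warnings;
  missing columns are hard errors.
* All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence`; identical seeds give byte-identical outputs. CLI outputs
  carry a provenance header (version, config hash, seed).
* Hot loops (alignment, candidate collection, error injection) are numba
  kernels over uint8-encoded sequences; 100,000 reads against a
  70,000-barcode whitelist demultiplex in well under a minute on one CPU.
  Fisher/chi-squared tests and FDR corrections use scipy and statsmodels;
  tests check them against enumeration and closed-form oracles.

## Known limitations

* The i.i.d. error model, as discussed above.
* The linker sequence and 8+6 barcode split are conventions, not vendor
  specifications; both are configurable.
* The greedy UMI clustering is order-dependent (as specified) and makes no
  exactness claim versus optimal clustering.
* Candidate exons come from observed reads only; exons never seen included
  in any read cannot be discovered.
* The `run-all` pipeline replaces genome alignment and gene assignment
  (out of scope) with truth-joined synthetic annotation; it exercises the
  package's own stages end to end, not an aligner.
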