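# beadsplice

Spatially barcoded long-read (ONT cDNA) experiments on Curio-style slides tag
every molecule with a 14 bp bead barcode — split in two parts around a fixed
linker — plus a 9 bp UMI and a poly(T) stretch. Demultiplexing such reads is
hard: there are ~70,000 barcodes per slide, per-base error rates are several
percent, and read truncation can delete the barcode outright. `beadsplice`
implements the downstream computational toolkit for these experiments:

* **Barcode/UMI calling** — per read: sliding-window poly(T) detection;
  primer and linker location by k-mer prefilter (k=6 / k=5) plus
  Smith–Waterman local alignment; whitelist candidates from a k-mer index
  (k=6) scored with Smith–Waterman (+1 match, −1 mismatch/indel, maximum
  score = barcode length = 14); UMI taken between barcode end and poly(T)
  start; automatic reverse-complement retry. Calls below a minimal score
  (default 13) or with a tied top score are rejected.
* **PCR-duplicate removal** — greedy representative-UMI clustering within
  each (gene, barcode) group at edit distance ≤ 2 (end gaps free up to the
  threshold), keeping the read covering the most splice junctions.
* **Differential cassette-exon inclusion** — per-exon A/B/C/D/E support
  counts, PSI = (A+B+C)/(A+B+C+D), alternative-exon filters
  (A+B+C+D ≥ 10, purity ≥ 0.8, leftPSI/rightPSI ∈ [0.05, 0.95]), two-sided
  Fisher exact tests on inclusion-vs-exclusion 2×2 tables, and
  Benjamini–Yekutieli correction; significant = FDR < 0.05 and |ΔPSI| ≥ 0.2.
* **Poly(A)/TSS/splice-site/isoform usage** — per-gene 2×K tables (K ≤ 11:
  top 10 categories + "other"), Pearson chi-squared tests,
  Benjamini–Hochberg correction, and the non-negative effect size
  ΔΠ = sum of the two largest positive per-category usage changes; plus
  strand-aware last-exon-length summaries.
* **Power-equalized downsampling** — balanced resampling (20 reads/exon,
  50 exons, ≤1 exon/gene, 100 iterations by default) so two contrasts are
  tested at identical power, compared with a Wilcoxon rank-sum test.
* **Read simulator + benchmark** — molecule assembly from a shared layout,
  i.i.d. per-base errors (1.4% substitution / 2.0% insertion / 1.0%
  deletion), optional barcode-proximal truncation, strand flipping, PCR
  duplication, and exact truth tables for precision/recall scoring.

Intended users: developers of spatial long-read pipelines and analysts who
need a transparent, testable reference implementation of these steps.

## Worked example

Simulate 5,000 reads against a 20,000-barcode whitelist, call barcodes, and
score the calls against the simulation truth:

```bash
beadsplice simulate --n-molecules 5000 --n-barcodes 20000 --seed 7 \
    --out-fastq reads.fq --out-truth truth.tsv --out-whitelist wl.txt
beadsplice demux --fastq reads.fq --whitelist wl.txt --min-score 11 --out calls.tsv
beadsplice benchmark --calls calls.tsv --truth truth.tsv --out bench.tsv
```

`demux` reports how far each read got through the detection pipeline:

```
called 5000 reads; stages: {'ok': 2797, 'no_polyT': 1763, 'no_linker': 36,
                            'no_primer': 246, 'low_score': 158}
```

and `bench.tsv` contains precision/recall per minimal score:

```
threshold  tp    fp  fn    precision  recall
11         2745  52  2203  98.1409    54.9000
12         2623  11  2366  99.5824    52.4600
13         1905   2  3093  99.8951    38.1000
14         1510   0  3490  100.0000   30.2000
```

Reading this: with truncation enabled (the default, emulating real ONT
libraries) roughly half the reads lose their barcode region entirely —
recall tops out near 55% — while precision is high and rises with the score
cutoff, reaching 100% at an exact 14/14 match. Raising the cutoff trades
recall for precision monotonically.

The other stages run the same way: `beadsplice dedup`, `test-exons`,
`test-usage`, `downsample`, and `run-all` (simulate → demux → dedup → test
in one command); see `beadsplice <cmd> --help`.

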