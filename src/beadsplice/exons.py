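"""Differential cassette-exon inclusion between two groups of spliced reads.

For a candidate exon ``[s, e]`` every gene-assigned, exon-overlapping read
falls in exactly one category:

* **A** — contains the exon block with both flanking splice sites;
* **B** — an intron ends at ``s-1`` and the read's right end lies on the exon;
* **C** — an intron starts at ``e+1`` and the read's left end lies on the exon;
* **D** — an intron of the read spans the exon (skipping);
* **E** — any other overlap.

Percent spliced-in is ``PSI = (A+B+C)/(A+B+C+D)``, with one-sided variants
``leftPSI = (A+B)/(A+B+D)`` and ``rightPSI = (A+C)/(A+C+D)``.  An exon is an
alternative cassette when, on the pooled two-group reads, ``A+B+C+D >= 10``,
``(A+B+C+D)/(A+B+C+D+E) >= 0.8`` and both one-sided PSIs lie in
``[0.05, 0.95]``.  Group inclusion (A+B+C) versus exclusion (D) counts form a
2x2 table tested with a two-sided Fisher exact test when both groups have
``A+B+C+D >= 10`` and at least 3 of 4 cells have expected counts >= 5;
p-values are Benjamini-Yekutieli corrected.  An exon is called significant at
FDR < 0.05 and ``|deltaPSI| >= 0.2``.

"Left"/"right" are genomic (coordinate) directions; strand is carried for
reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import ExonId, ReadModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
DEFAULT_PURITY = 0.8
DEFAULT_PSI_BOUNDS = (0.05, 0.95)
DEFAULT_FDR = 0.05
DEFAULT_MIN_DELTA_PSI = 0.2


@dataclass(frozen=True)
class ExonCounts:
    """A-E support counts for one exon in one read set."""

    exon: ExonId
    A: int = 0
    B: int = 0
    C: int = 0
    D: int = 0
    E: int = 0

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D, self.E) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def inclusion(self) -> int:
        return self.A + self.B + self.C

    @property
    def informative(self) -> int:
        return self.A + self.B + self.C + self.D

    @property
    def total(self) -> int:
        return self.informative + self.E

    @property
    def psi(self) -> float | None:
        return None if self.informative == 0 else self.inclusion / self.informative

    @property
    def left_psi(self) -> float | None:
        den = self.A + self.B + self.D
        return None if den == 0 else (self.A + self.B) / den

    @property
    def right_psi(self) -> float | None:
        den = self.A + self.C + self.D
        return None if den == 0 else (self.A + self.C) / den

    def __add__(self, other: "ExonCounts") -> "ExonCounts":
        if other.exon != self.exon:
            raise ValueError("cannot add counts for different exons")
        return ExonCounts(
            self.exon,
            self.A + other.A,
            self.B + other.B,
            self.C + other.C,
            self.D + other.D,
            self.E + other.E,
        )


@dataclass(frozen=True)
class ExonTestResult:
    exon: ExonId
    gene: str
    counts_g1: ExonCounts
    counts_g2: ExonCounts
    psi_g1: float | None
    psi_g2: float | None
    delta_psi: float | None
    p: float | None
    fdr: float | None = None
    tested: bool = False
    significant: bool = False
    filter_reason: str = ""


def eligible_reads(
    records: Iterable[ReadModel],
    splice_consensus: Mapping[str, bool] | None = None,
) -> Iterator[ReadModel]:
    """Keep spliced reads (>=1 intron); with consensus flags supplied, only
    reads whose introns all respect the splice-site consensus."""
    for r in records:
        if r.n_introns < 1:
            continue
        if splice_consensus is not None and not splice_consensus.get(r.read_id, False):
            continue
        yield r


def internal_exons(reads: Iterable[ReadModel]) -> set[tuple[str, int, int, str]]:
    """Distinct internal exon blocks (flanked by introns within some read)."""
    out: set[tuple[str, int, int, str]] = set()
    for r in reads:
        for i, blk in enumerate(r.exon_blocks):
            if 0 < i < len(r.exon_blocks) - 1:
                out.add((r.chrom, blk[0], blk[1], r.strand))
    return out


def count_exon_support(exon: ExonId, reads: Iterable[ReadModel]) -> ExonCounts:
    """Assign each gene-assigned, exon-overlapping read to exactly one of
    A/B/C/D/E (in that priority order)."""
    s, e = exon.start, exon.end
    A = B = C = D = E = 0
    for r in reads:
        if r.chrom != exon.chrom:
            continue
        left, right = r.span
        if right < s or left > e:
            continue  # no overlap
        has_block = (s, e) in r.exon_blocks
        left_site = any(ie == s - 1 for _, ie in r.intron_chain)
        right_site = any(ib == e + 1 for ib, _ in r.intron_chain)
        if has_block and left_site and right_site:
            A += 1
        elif left_site and s <= right <= e:
            B += 1
        elif right_site and s <= left <= e:
            C += 1
        elif any(ib < s and ie > e for ib, ie in r.intron_chain):
            D += 1
        else:
            E += 1
    return ExonCounts(exon, A, B, C, D, E)


def is_alternative(
    counts: ExonCounts,
    min_reads: int = DEFAULT_MIN_READS,
    min_purity: float = DEFAULT_PURITY,
    psi_bounds: tuple[float, float] = DEFAULT_PSI_BOUNDS,
) -> tuple[bool, str]:
    """Alternative-cassette filters on pooled two-group counts; the reason
    names the first failed filter."""
    if counts.informative < min_reads:
        return False, f"informative {counts.informative} < {min_reads}"
    if counts.total > 0 and counts.informative / counts.total < min_purity:
        return False, f"purity {counts.informative / counts.total:.3f} < {min_purity}"
    lo, hi = psi_bounds
    for name, value in (("leftPSI", counts.left_psi), ("rightPSI", counts.right_psi)):
        if value is None or not lo <= value <= hi:
            shown = "NA" if value is None else f"{value:.3f}"
            return False, f"{name} {shown} outside [{lo}, {hi}]"
    return True, ""


def _expected_counts(table: Sequence[Sequence[int]]) -> list[list[float]]:
    r0 = sum(table[0])
    r1 = sum(table[1])
    c0 = table[0][0] + table[1][0]
    c1 = table[0][1] + table[1][1]
    n = r0 + r1
    if n == 0:
        return [[0.0, 0.0], [0.0, 0.0]]
    return [[r0 * c0 / n, r0 * c1 / n], [r1 * c0 / n, r1 * c1 / n]]


def test_exon(
    c1: ExonCounts,
    c2: ExonCounts,
    gene: str = "",
    min_reads: int = DEFAULT_MIN_READS,
    min_expected: float = 5.0,
    min_expected_cells: int = 3,
) -> ExonTestResult:
    """Two-sided Fisher exact test of inclusion (A+B+C) vs exclusion (D)
    between two groups; untested when either group has < ``min_reads``
    informative reads or fewer than ``min_expected_cells`` cells of the 2x2
    table have expected counts >= ``min_expected``."""
    psi1, psi2 = c1.psi, c2.psi
    delta = None if psi1 is None or psi2 is None else psi2 - psi1
    base = ExonTestResult(c1.exon, gene, c1, c2, psi1, psi2, delta, None)
    if c1.informative < min_reads or c2.informative < min_reads:
        return replace(base, filter_reason=f"group informative reads < {min_reads}")
    table = [[c1.inclusion, c1.D], [c2.inclusion, c2.D]]
    if sum(table[0]) + sum(table[1]) == 0:
        return replace(base, filter_reason="empty table")
    expected = _expected_counts(table)
    n_ok = sum(1 for row in expected for v in row if v >= min_expected)
    if n_ok < min_expected_cells:
        return replace(
            base, filter_reason=f"only {n_ok} cells with expected >= {min_expected}"
        )
    _, p = fisher_exact(table, alternative="two-sided")
    return replace(base, p=float(p), tested=True)


def correct_by(results: Sequence[ExonTestResult]) -> list[ExonTestResult]:
    """Benjamini-Yekutieli adjusted FDR over the tested results."""
    tested = [r for r in results if r.tested and r.p is not None]
    if tested:
        fdrs = multipletests([r.p for r in tested], method="fdr_by")[1]
        fdr_by_id = {id(r): f for r, f in zip(tested, fdrs)}
    else:
        fdr_by_id = {}
    return [
        replace(r, fdr=float(fdr_by_id[id(r)])) if id(r) in fdr_by_id else r
        for r in results
    ]


def flag_significant(
    results: Sequence[ExonTestResult],
    max_fdr: float = DEFAULT_FDR,
    min_delta_psi: float = DEFAULT_MIN_DELTA_PSI,
) -> list[ExonTestResult]:
    return [
        replace(
            r,
            significant=(
                r.tested
                and r.fdr is not None
                and r.fdr < max_fdr
                and r.delta_psi is not None
                and abs(r.delta_psi) >= min_delta_psi
            ),
        )
        for r in results
    ]


@dataclass
class ExonTestSummary:
    n_candidates: int
    n_tested: int
    n_significant: int
    percent_significant: float | None
    delta_psi: list[float] = field(default_factory=list, repr=False)


def summarize(results: Sequence[ExonTestResult]) -> ExonTestSummary:
    tested = [r for r in results if r.tested]
    n_sig = sum(1 for r in tested if r.significant)
    pct = None if not tested else 100.0 * n_sig / len(tested)
    return ExonTestSummary(
        n_candidates=len(results),
        n_tested=len(tested),
        n_significant=n_sig,
        percent_significant=pct,
        delta_psi=[r.delta_psi for r in tested if r.delta_psi is not None],
    )


def run_exon_tests(
    records: Iterable[ReadModel],
    group_1: str,
    group_2: str,
    min_reads: int = DEFAULT_MIN_READS,
    splice_consensus: Mapping[str, bool] | None = None,
    max_fdr: float = DEFAULT_FDR,
    min_delta_psi: float = DEFAULT_MIN_DELTA_PSI,
) -> list[ExonTestResult]:
    """End-to-end exon pipeline: eligibility, candidate discovery on pooled
    reads, filters, per-group Fisher tests, BY correction, significance."""
    by_gene: dict[str, list[ReadModel]] = {}
    for r in eligible_reads(records, splice_consensus):
        if r.group in (group_1, group_2):
            by_gene.setdefault(r.gene_id, []).append(r)
    results: list[ExonTestResult] = []
    for gene in sorted(by_gene):
        reads = by_gene[gene]
        g1 = [r for r in reads if r.group == group_1]
        g2 = [r for r in reads if r.group == group_2]
        for chrom, s, e, strand in sorted(internal_exons(reads)):
            exon = ExonId(chrom, s, e, strand)
            pooled = count_exon_support(exon, reads)
            ok, reason = is_alternative(pooled, min_reads)
            c1 = count_exon_support(exon, g1)
            c2 = count_exon_support(exon, g2)
            if not ok:
                results.append(
                    ExonTestResult(
                        exon, gene, c1, c2, c1.psi, c2.psi,
                        None if c1.psi is None or c2.psi is None else c2.psi - c1.psi,
                        None, filter_reason=reason,
                    )
                )
                continue
            results.append(test_exon(c1, c2, gene, min_reads))
    return flag_significant(correct_by(results), max_fdr, min_delta_psi)


EXON_RESULT_COLUMNS = (
    "exon",
    "gene",
    "A1", "B1", "C1", "D1", "E1",
    "A2", "B2", "C2", "D2", "E2",
    "psi_g1", "psi_g2", "delta_psi",
    "p", "fdr", "tested", "significant", "filter_reason",
)


def write_exon_results(results: Iterable[ExonTestResult], path, provenance=None) -> int:
    from pathlib import Path

    from .io import _open_text

    def fmt(x):
        if x is None:
            return "."
        if isinstance(x, bool):
            return str(int(x))
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    n = 0
    with _open_text(Path(path), "wt") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(EXON_RESULT_COLUMNS) + "\n")
        for r in results:
            c1, c2 = r.counts_g1, r.counts_g2
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        str(r.exon), r.gene,
                        c1.A, c1.B, c1.C, c1.D, c1.E,
                        c2.A, c2.B, c2.C, c2.D, c2.E,
                        r.psi_g1, r.psi_g2, r.delta_psi,
                        r.p, r.fdr, r.tested, r.significant, r.filter_reason or ".",
                    )
                )
                + "\n"
            )
            n += 1
    return n
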