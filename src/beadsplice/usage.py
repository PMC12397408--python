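"""2xN usage tests: poly(A) sites, TSS, splice-site and full-isoform usage.

Unlike a cassette exon with its two states, a gene may use many poly(A)
sites, transcription start sites or isoforms.  Per gene the observed feature
categories are ranked by pooled abundance (ID 1 = most abundant, ties broken
by feature identifier), collapsed to the top 10 plus an "other" row, and the
2-group x K count matrix (K <= 11) is tested for independence with a Pearson
chi-squared test (no continuity correction) and Benjamini-Hochberg
correction.  The effect size deltaPI is the sum of the two largest positive
per-category usage changes, a non-negative fraction bounded by 1.

Full-isoform identity is the (TSS, intron chain, poly(A) site) triple and
requires all three parts on a read; acceptor/donor tests reuse the same 2xN
machinery on per-intron splice-site counts (each read contributes one count
per intron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .io import ReadModel

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("polyA", "TSS", "acceptor", "donor", "isoform")
MAX_CATEGORIES = 11  # top 10 + "other"
DEFAULT_MIN_READS = 10
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class UsageTable:
    """Per-gene 2 x K count matrix (K <= 11) over ranked feature categories."""

    gene: str
    feature_kind: str
    categories: tuple[Hashable, ...]
    counts: tuple[tuple[int, ...], tuple[int, ...]]  # rows: group 1, group 2

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if len(self.categories) > MAX_CATEGORIES:
            raise ValueError(f"more than {MAX_CATEGORIES} categories")
        for row in self.counts:
            if len(row) != len(self.categories):
                raise ValueError("row length != number of categories")
            if any(v < 0 for v in row):
                raise ValueError("negative count")

    @property
    def row_totals(self) -> tuple[int, int]:
        return sum(self.counts[0]), sum(self.counts[1])

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class UsageTestResult:
    gene: str
    feature_kind: str
    p: float | None
    delta_pi: float | None
    tested: bool
    fdr: float | None = None
    n_categories: int = 0
    n_reads: int = 0
    reason: str = ""


def read_features(read: ReadModel, feature_kind: str) -> list[Hashable]:
    """Feature identifiers one read contributes to a usage table (possibly
    none, possibly several for splice-site kinds)."""
    if feature_kind == "polyA":
        return [] if read.polya is None else [read.polya]
    if feature_kind == "TSS":
        return [] if read.tss is None else [read.tss]
    if feature_kind == "acceptor":
        # intron 3' end in transcription direction
        return [ie for _, ie in read.intron_chain] if read.strand == "+" else [
            ib for ib, _ in read.intron_chain
        ]
    if feature_kind == "donor":
        return [ib for ib, _ in read.intron_chain] if read.strand == "+" else [
            ie for _, ie in read.intron_chain
        ]
    if feature_kind == "isoform":
        if read.tss is None or read.polya is None:
            return []
        return [(read.tss, read.intron_chain, read.polya)]
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def build_usage_table(
    reads: Iterable[ReadModel],
    feature_kind: str,
    group_1: str,
    group_2: str,
    gene: str | None = None,
    max_categories: int = MAX_CATEGORIES,
) -> UsageTable | None:
    """Pooled-abundance-ranked, top-(K-1)+other usage table for one gene.

    Returns None when no read contributes a feature.  Ties in pooled
    abundance are broken by the (stringified) feature identifier.
    """
    counts: dict[Hashable, list[int]] = {}
    gene_id = gene
    for r in reads:
        if gene_id is None:
            gene_id = r.gene_id
        elif r.gene_id != gene_id:
            raise ValueError(f"read {r.read_id} belongs to {r.gene_id}, not {gene_id}")
        if r.group == group_1:
            row = 0
        elif r.group == group_2:
            row = 1
        else:
            continue
        for feat in read_features(r, feature_kind):
            counts.setdefault(feat, [0, 0])[row] += 1
    if not counts:
        return None
    ranked = sorted(counts, key=lambda f: (-sum(counts[f]), str(f)))
    if len(ranked) > max_categories:
        top = ranked[: max_categories - 1]
        rest = ranked[max_categories - 1 :]
        other = [0, 0]
        for f in rest:
            other[0] += counts[f][0]
            other[1] += counts[f][1]
        categories: tuple[Hashable, ...] = tuple(top) + ("other",)
        row1 = tuple(counts[f][0] for f in top) + (other[0],)
        row2 = tuple(counts[f][1] for f in top) + (other[1],)
    else:
        categories = tuple(ranked)
        row1 = tuple(counts[f][0] for f in ranked)
        row2 = tuple(counts[f][1] for f in ranked)
    return UsageTable(gene_id or "", feature_kind, categories, (row1, row2))


def test_usage(
    table: UsageTable,
    min_reads: int = DEFAULT_MIN_READS,
    warn_low_expected: bool = True,
) -> UsageTestResult:
    """Pearson chi-squared independence test on the 2xK table (no continuity
    correction); single-category or degenerate tables are untested."""
    n1, n2 = table.row_totals
    n = n1 + n2
    base = UsageTestResult(
        table.gene, table.feature_kind, None, delta_pi(table), False,
        n_categories=table.n_categories, n_reads=n,
    )
    if n < min_reads:
        return replace(base, delta_pi=None, reason=f"total reads {n} < {min_reads}")
    if table.n_categories < 2:
        return replace(base, reason="single category")
    if n1 == 0 or n2 == 0:
        return replace(base, delta_pi=None, reason="empty group")
    obs = np.asarray(table.counts, dtype=float)
    stat, p, _, expected = chi2_contingency(obs, correction=False)
    if warn_low_expected and (expected < 5).mean() > 0.2:
        logger.warning(
            "gene %s (%s): >20%% of expected counts < 5; chi-squared approximation weak",
            table.gene, table.feature_kind,
        )
    return replace(base, p=float(p), tested=True)


def delta_pi(table: UsageTable) -> float | None:
    """Sum of the two largest positive per-category usage changes (fraction
    of group 2 minus fraction of group 1); 0 when no category gains."""
    n1, n2 = table.row_totals
    if n1 == 0 or n2 == 0:
        return None
    pi1 = np.asarray(table.counts[0], dtype=float) / n1
    pi2 = np.asarray(table.counts[1], dtype=float) / n2
    gains = np.sort(pi2 - pi1)[::-1]
    return float(sum(g for g in gains[:2] if g > 0))


def correct_bh(results: Sequence[UsageTestResult]) -> list[UsageTestResult]:
    """Benjamini-Hochberg step-up FDR over the tested genes."""
    tested = [r for r in results if r.tested and r.p is not None]
    if tested:
        fdrs = multipletests([r.p for r in tested], method="fdr_bh")[1]
        fdr_by_id = {id(r): float(f) for r, f in zip(tested, fdrs)}
    else:
        fdr_by_id = {}
    return [replace(r, fdr=fdr_by_id.get(id(r))) if r.tested else r for r in results]


def run_usage_tests(
    records: Iterable[ReadModel],
    feature_kind: str,
    group_1: str,
    group_2: str,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[UsageTestResult]:
    """Per-gene 2xN usage tests with BH correction, genes in sorted order."""
    by_gene: dict[str, list[ReadModel]] = {}
    for r in records:
        if r.group in (group_1, group_2):
            by_gene.setdefault(r.gene_id, []).append(r)
    results = []
    for gene in sorted(by_gene):
        table = build_usage_table(by_gene[gene], feature_kind, group_1, group_2, gene)
        if table is None:
            results.append(
                UsageTestResult(gene, feature_kind, None, None, False, reason="no features")
            )
            continue
        results.append(test_usage(table, min_reads))
    return correct_bh(results)


def last_exon_length(read: ReadModel) -> int:
    """Length of the strand-wise final exon block (the exon carrying the
    poly(A) site), 1-based inclusive coordinates."""
    block = read.exon_blocks[-1] if read.strand == "+" else read.exon_blocks[0]
    return block[1] - block[0] + 1


def last_exon_lengths(
    records: Iterable[ReadModel],
    genes: set[str] | None = None,
) -> dict[tuple[str, str], float]:
    """Mean last-exon length per (gene, group) over reads with a poly(A) site.

    ``genes`` restricts the computation, e.g. to genes with or without
    developmentally regulated poly(A) usage (|deltaPI| above/below 0.2).
    """
    sums: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.polya is None:
            continue
        if genes is not None and r.gene_id not in genes:
            continue
        acc = sums.setdefault((r.gene_id, r.group), [0.0, 0.0])
        acc[0] += last_exon_length(r)
        acc[1] += 1.0
    return {key: s / n for key, (s, n) in sums.items()}


USAGE_RESULT_COLUMNS = (
    "gene", "feature", "n_reads", "n_categories", "p", "fdr", "delta_pi", "tested", "reason",
)


def write_usage_results(results: Iterable[UsageTestResult], path, provenance=None) -> int:
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
        fh.write("\t".join(USAGE_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        r.gene, r.feature_kind, r.n_reads, r.n_categories,
                        r.p, r.fdr, r.delta_pi, r.tested, r.reason or ".",
                    )
                )
                + "\n"
            )
            n += 1
    return n
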