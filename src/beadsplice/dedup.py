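"""PCR-duplicate removal by greedy representative-UMI clustering.

Reads sharing an assigned gene and a bead barcode are candidate PCR
duplicates.  Within such a group we make a single greedy pass in a
deterministic order, maintaining a list of representative UMIs: a read whose
UMI is within edit distance 2 of a representative joins the closest one
(first-collected wins ties), otherwise its UMI becomes a new representative.
Leading and trailing indels are free when comparing UMIs, since UMI
boundaries on a noisy read are themselves uncertain.  Per cluster the read
covering the most splice junctions is kept (ties: lexicographically smallest
read id); the rest are discarded as PCR duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import ReadModel

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 2


def umi_distance(u1: str, u2: str, end_gap_cap: int = DEFAULT_MAX_DIST) -> int:
    """Levenshtein distance with free (cost-0) leading and trailing gaps.

    End gaps model UMI boundary slippage on a noisy read, so they are free
    only up to ``end_gap_cap`` bases per end (unbounded free end gaps would
    let any two sequences slide past each other at distance 0).  The default
    cap equals the clustering threshold.
    """
    if not u1 or not u2:
        raise ValueError("UMIs must be non-empty")
    n, m = len(u1), len(u2)
    cap = end_gap_cap
    prev = [max(0, j - cap) for j in range(m + 1)]
    best = prev[m] + max(0, n - cap)  # u1 entirely as overhang
    for i in range(1, n + 1):
        cur = [max(0, i - cap)] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if u1[i - 1] == u2[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
        # trailing overhang of u1 below row i
        best = min(best, prev[m] + max(0, n - i - cap))
    for j in range(m + 1):
        best = min(best, prev[j] + max(0, m - j - cap))
    return best


@dataclass(frozen=True)
class UmiCluster:
    representative_umi: str
    member_read_ids: tuple[str, ...]
    kept_read_id: str


@dataclass(frozen=True)
class MoleculeGroup:
    """All reads sharing one (gene, barcode) pair."""

    gene_id: str
    barcode: str
    reads: tuple[ReadModel, ...]

    def __post_init__(self) -> None:
        for r in self.reads:
            if r.gene_id != self.gene_id or r.barcode != self.barcode:
                raise ValueError(
                    f"read {r.read_id} ({r.gene_id}, {r.barcode}) does not belong to "
                    f"group ({self.gene_id}, {self.barcode})"
                )


def dedup_group(
    group: MoleculeGroup,
    max_dist: int = DEFAULT_MAX_DIST,
    presort: bool = False,
) -> tuple[list[ReadModel], list[UmiCluster]]:
    """Greedy single-pass UMI clustering of one (gene, barcode) group.

    Reads are processed in input order (``presort=True`` sorts by
    (n_introns desc, read_id) first; the greedy pass is order-dependent).
    Returns the kept reads (one per cluster, most splice junctions) and the
    clusters themselves.
    """
    reads = list(group.reads)
    if presort:
        reads.sort(key=lambda r: (-r.n_introns, r.read_id))
    reps: list[str] = []
    members: list[list[ReadModel]] = []
    for read in reads:
        best = -1
        best_d = max_dist + 1
        for i, rep in enumerate(reps):
            d = umi_distance(read.umi, rep)
            if d < best_d:  # first-collected representative wins ties
                best_d = d
                best = i
        if best >= 0 and best_d <= max_dist:
            members[best].append(read)
        else:
            reps.append(read.umi)
            members.append([read])
    kept: list[ReadModel] = []
    clusters: list[UmiCluster] = []
    for rep, mem in zip(reps, members):
        keep = min(mem, key=lambda r: (-r.n_introns, r.read_id))
        kept.append(keep)
        clusters.append(UmiCluster(rep, tuple(r.read_id for r in mem), keep.read_id))
    return kept, clusters


@dataclass
class DedupStats:
    n_groups: int = 0
    n_reads: int = 0
    n_kept: int = 0
    n_unassigned: int = 0

    @property
    def n_duplicates(self) -> int:
        return self.n_reads - self.n_kept


def dedup_all(
    records: Iterable[ReadModel],
    max_dist: int = DEFAULT_MAX_DIST,
    presort: bool = False,
    stats: DedupStats | None = None,
) -> Iterator[ReadModel]:
    """Partition records by (gene, barcode), dedup each group, emit kept reads.

    Records without a gene assignment (empty or ".") are passed through
    untouched with a warning counter.  Output order: groups in first-seen
    order, kept reads in cluster order.
    """
    groups: dict[tuple[str, str], list[ReadModel]] = {}
    passthrough: list[ReadModel] = []
    n_reads = 0
    for r in records:
        if not r.gene_id or r.gene_id == ".":
            passthrough.append(r)
            continue
        n_reads += 1
        groups.setdefault((r.gene_id, r.barcode), []).append(r)
    if passthrough:
        logger.warning("%d records lack a gene assignment; passed through", len(passthrough))
    n_kept = 0
    for (gene, bc), reads in groups.items():
        kept, _ = dedup_group(MoleculeGroup(gene, bc, tuple(reads)), max_dist, presort)
        n_kept += len(kept)
        yield from kept
    yield from passthrough
    if stats is not None:
        stats.n_groups = len(groups)
        stats.n_reads = n_reads
        stats.n_kept = n_kept
        stats.n_unassigned = len(passthrough)
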