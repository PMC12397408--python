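"""Readers/writers for every file the pipeline touches.

Formats
-------
* barcode whitelist: plain text or TSV, first column one fixed-length barcode
  per line (slides ship with ~70,000 of them);
* AllInfo: per-read TSV with 11 columns describing a barcoded, deduplicated,
  spliced read (see :class:`ReadModel` and :data:`ALLINFO_COLUMNS`);
* simulation truth table: TSV mapping read ids to the latent variables of the
  simulator;
* FASTQ/FASTA via Biopython, transparently gzipped.

Coordinates are 1-based inclusive throughout.  Intron/exon chains are
serialized ``chrom:strand:start-end;start-end;...`` (dialect v1); absent
TSS/poly(A) values are encoded as ``"."`` — absence is first-class, since only
a minority of long reads carry a confident TSS.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALLINFO_COLUMNS = (
    "read_id",
    "gene_id",
    "group",
    "barcode",
    "umi",
    "intron_chain",
    "tss",
    "polya",
    "exon_chain",
    "novelty",
    "n_introns",
)

TRUTH_COLUMNS = (
    "read_id",
    "true_barcode",
    "true_umi",
    "transcript_id",
    "truncated",
    "strand_flipped",
    "barcode_intact",
)

MISSING = "."


class WhitelistError(ValueError):
    """Raised for malformed barcode whitelist files."""


class AllInfoError(ValueError):
    """Raised for structurally unusable AllInfo files."""


@dataclass(frozen=True)
class Whitelist:
    """Ordered set of fixed-length bead barcodes."""

    barcodes: tuple[str, ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise WhitelistError("empty whitelist")
        length = len(self.barcodes[0])
        seen: set[str] = set()
        for i, bc in enumerate(self.barcodes):
            if len(bc) != length:
                raise WhitelistError(
                    f"barcode {bc!r} (entry {i + 1}) has length {len(bc)}, expected {length}"
                )
            if set(bc) - set("ACGT"):
                raise WhitelistError(f"barcode {bc!r} (entry {i + 1}) has non-ACGT characters")
            if bc in seen:
                raise WhitelistError(f"duplicate barcode {bc!r} (entry {i + 1})")
            seen.add(bc)
        object.__setattr__(self, "_set", frozenset(seen))

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, bc: object) -> bool:
        return bc in self._set  # type: ignore[attr-defined]

    def __iter__(self) -> Iterator[str]:
        return iter(self.barcodes)


@dataclass(frozen=True)
class ExonId:
    """One genomic exon, serialized ``chrom_start_end_strand``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}_{self.strand}"

    @classmethod
    def parse(cls, s: str) -> "ExonId":
        chrom, start, end, strand = s.rsplit("_", 3)
        return cls(chrom, int(start), int(end), strand)


@dataclass(frozen=True)
class ReadModel:
    """One barcoded, deduplicated spliced read (an AllInfo record).

    ``intron_chain`` and ``exon_blocks`` are sorted, non-overlapping 1-based
    inclusive intervals that interleave without gaps: each intron spans exactly
    the gap between two consecutive exon blocks.
    """

    read_id: str
    gene_id: str
    group: str
    barcode: str
    umi: str
    intron_chain: tuple[tuple[int, int], ...]
    exon_blocks: tuple[tuple[int, int], ...]
    chrom: str
    strand: str
    tss: int | None = None
    polya: int | None = None
    novelty: str = "known"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.novelty not in ("known", "novel"):
            raise ValueError(f"bad novelty {self.novelty!r}")
        if not self.exon_blocks:
            raise ValueError("read must have at least one exon block")
        if len(self.intron_chain) != len(self.exon_blocks) - 1:
            raise ValueError(
                f"{len(self.intron_chain)} introns do not interleave "
                f"{len(self.exon_blocks)} exon blocks"
            )
        prev_end = None
        for i, (s, e) in enumerate(self.exon_blocks):
            if s > e:
                raise ValueError(f"exon block {(s, e)} inverted")
            if prev_end is not None:
                intron = self.intron_chain[i - 1]
                if intron != (prev_end + 1, s - 1) or intron[0] > intron[1]:
                    raise ValueError(
                        f"intron {intron} does not fill gap between exon blocks "
                        f"({prev_end}, {s})"
                    )
            prev_end = e

    @property
    def n_introns(self) -> int:
        return len(self.intron_chain)

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_blocks[0][0], self.exon_blocks[-1][1]

    def with_group(self, group: str) -> "ReadModel":
        return replace(self, group=group)


@dataclass(frozen=True)
class TruthRecord:
    """Latent variables of one simulated read."""

    read_id: str
    true_barcode: str
    true_umi: str
    transcript_id: str
    truncated: bool
    strand_flipped: bool
    barcode_intact: bool = True


# ---------------------------------------------------------------------------
# whitelist


def read_whitelist(path: str | Path, on_duplicate: str = "error") -> Whitelist:
    """Read a barcode whitelist (first column of a text/TSV file).

    Mixed barcode lengths or non-ACGT characters are hard errors naming the
    offending line.  Duplicates are errors by default (``on_duplicate="drop"``
    keeps the first occurrence instead).
    """
    path = Path(path)
    barcodes: list[str] = []
    seen: set[str] = set()
    length: int | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bc = line.split("\t")[0].split()[0].upper()
            if set(bc) - set("ACGT"):
                raise WhitelistError(f"{path}:{lineno}: non-ACGT barcode {bc!r}")
            if length is None:
                length = len(bc)
            elif len(bc) != length:
                raise WhitelistError(
                    f"{path}:{lineno}: barcode {bc!r} has length {len(bc)}, expected {length}"
                )
            if bc in seen:
                if on_duplicate == "drop":
                    continue
                raise WhitelistError(f"{path}:{lineno}: duplicate barcode {bc!r}")
            seen.add(bc)
            barcodes.append(bc)
    if not barcodes:
        raise WhitelistError(f"{path}: no barcodes found")
    logger.info("read %d barcodes of length %d from %s", len(barcodes), length, path)
    return Whitelist(tuple(barcodes), source_path=str(path))


# ---------------------------------------------------------------------------
# AllInfo


def _format_chain(chrom: str, strand: str, intervals: Sequence[tuple[int, int]]) -> str:
    if not intervals:
        return MISSING
    body = ";".join(f"{s}-{e}" for s, e in intervals)
    return f"{chrom}:{strand}:{body}"


def _parse_chain(token: str) -> tuple[str, str, tuple[tuple[int, int], ...]]:
    chrom, strand, body = token.split(":", 2)
    if strand not in "+-":
        raise ValueError(f"bad strand in chain token {token!r}")
    intervals = []
    for part in body.split(";"):
        s, e = part.split("-")
        intervals.append((int(s), int(e)))
    return chrom, strand, tuple(intervals)


def _coord(value: int | None) -> str:
    return MISSING if value is None else str(value)


def format_allinfo_row(r: ReadModel) -> str:
    fields = (
        r.read_id,
        r.gene_id,
        r.group,
        r.barcode,
        r.umi,
        _format_chain(r.chrom, r.strand, r.intron_chain),
        _coord(r.tss),
        _coord(r.polya),
        _format_chain(r.chrom, r.strand, r.exon_blocks),
        r.novelty,
        str(r.n_introns),
    )
    return "\t".join(fields)


def parse_allinfo_row(fields: Sequence[str]) -> ReadModel:
    if len(fields) != len(ALLINFO_COLUMNS):
        raise ValueError(f"expected {len(ALLINFO_COLUMNS)} columns, got {len(fields)}")
    chrom, strand, exon_blocks = _parse_chain(fields[8])
    if fields[5] == MISSING:
        intron_chain: tuple[tuple[int, int], ...] = ()
    else:
        ichrom, istrand, intron_chain = _parse_chain(fields[5])
        if (ichrom, istrand) != (chrom, strand):
            raise ValueError("intron and exon chains disagree on chrom/strand")
    model = ReadModel(
        read_id=fields[0],
        gene_id=fields[1],
        group=fields[2],
        barcode=fields[3],
        umi=fields[4],
        intron_chain=intron_chain,
        exon_blocks=exon_blocks,
        chrom=chrom,
        strand=strand,
        tss=None if fields[6] == MISSING else int(fields[6]),
        polya=None if fields[7] == MISSING else int(fields[7]),
        novelty=fields[9],
    )
    if int(fields[10]) != model.n_introns:
        raise ValueError(
            f"declared n_introns={fields[10]} but chain has {model.n_introns} introns"
        )
    return model


def parse_allinfo(path: str | Path, header: bool = False) -> Iterator[ReadModel]:
    """Stream validated :class:`ReadModel` records from an AllInfo TSV.

    Malformed rows are counted and skipped with a warning; a wrong column
    count on the first data row is a hard error (missing mandatory columns).
    """
    path = Path(path)
    n_bad = 0
    first_data_row = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                continue
            fields = line.split("\t")
            if len(fields) != len(ALLINFO_COLUMNS) and first_data_row:
                raise AllInfoError(
                    f"{path}:{lineno}: expected {len(ALLINFO_COLUMNS)} columns, "
                    f"got {len(fields)} — missing mandatory column(s)?"
                )
            first_data_row = False
            try:
                yield parse_allinfo_row(fields)
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)


def write_allinfo(
    records: Iterable[ReadModel],
    path: str | Path,
    header: bool = False,
    provenance: str | None = None,
) -> int:
    """Write records as AllInfo TSV; returns the number of rows written."""
    n = 0
    with _open_text(Path(path), "wt") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        if header:
            fh.write("\t".join(ALLINFO_COLUMNS) + "\n")
        for r in records:
            fh.write(format_allinfo_row(r) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# simulation truth table


def write_truth(records: Iterable[TruthRecord], path: str | Path,
                provenance: str | None = None) -> int:
    n = 0
    with _open_text(Path(path), "wt") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.read_id,
                        r.true_barcode,
                        r.true_umi,
                        r.transcript_id,
                        str(int(r.truncated)),
                        str(int(r.strand_flipped)),
                        str(int(r.barcode_intact)),
                    )
                )
                + "\n"
            )
            n += 1
    return n


def read_truth(path: str | Path) -> Iterator[TruthRecord]:
    with _open_text(Path(path)) as fh:
        seen_ids: set[str] = set()
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            f = line.split("\t")
            if f[0] in seen_ids:
                raise ValueError(f"duplicate read_id {f[0]!r} in truth table")
            seen_ids.add(f[0])
            yield TruthRecord(
                read_id=f[0],
                true_barcode=f[1],
                true_umi=f[2],
                transcript_id=f[3],
                truncated=bool(int(f[4])),
                strand_flipped=bool(int(f[5])),
                barcode_intact=bool(int(f[6])) if len(f) > 6 else True,
            )


# ---------------------------------------------------------------------------
# FASTQ/FASTA


def _open_text(path: Path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs from FASTQ/FASTA, gz-transparent."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (read_id, sequence) pairs as FASTQ with flat quality strings."""
    n = 0
    with _open_text(Path(path), "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
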