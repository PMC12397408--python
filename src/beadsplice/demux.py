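"""Barcode and UMI calling on noisy spatial long reads.

Per read the caller (1) locates a poly(T) stretch by a sliding window,
(2) finds the amplification primer and the split-barcode linker in the region
preceding it using k-mer prefilters plus Smith-Waterman local alignment,
(3) extracts the candidate barcode sequence from the primer/linker
coordinates, (4) looks up whitelist candidates through a k-mer index (k=6)
and scores each with Smith-Waterman (+1 match, -1 mismatch/indel; maximum
score equals the barcode length, 14 for Curio-style slides), (5) takes the
UMI as the read subsequence between barcode end and poly(T) start.  If any
component is missing the whole procedure is retried on the reverse
complement.  Reads whose best alignment score falls below ``min_score``
(default 13) or whose top score is shared by several whitelist barcodes
(ambiguous) get no call and are dropped downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _engine
from ._seq import encode, revcomp_codes
from .io import Whitelist
from .layout import MoleculeLayout

logger = logging.getLogger(__name__)

# failure stages in pipeline order
NO_POLYT = "no_polyT"
NO_PRIMER = "no_primer"
NO_LINKER = "no_linker"
LOW_SCORE = "low_score"
OK = "ok"
STAGES = (NO_POLYT, NO_PRIMER, NO_LINKER, LOW_SCORE, OK)

POLYT_WINDOW = 16
POLYT_MIN_FRAC = 0.8
POLYT_MIN_T = 12
# primer/linker accepted at local-alignment score >= length - PRIMER_SLACK
PRIMER_SLACK = 4
SEARCH_SLACK = 20


class KmerIndex:
    """Key-value map from every k-mer to the set of indexed sequences.

    A candidate lookup for a query returns exactly the indexed sequences
    sharing at least one exact k-mer with it.
    """

    def __init__(self, sequences: Iterable[str], k: int):
        self.k = int(k)
        self.sequences = tuple(sequences)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        table: dict[str, set[str]] = {}
        for seq in self.sequences:
            if len(seq) < self.k:
                raise ValueError(f"sequence {seq!r} shorter than k={self.k}")
            for i in range(len(seq) - self.k + 1):
                table.setdefault(seq[i : i + self.k], set()).add(seq)
        self.table = table

    def lookup(self, query: str) -> set[str]:
        hits: set[str] = set()
        k = self.k
        for i in range(len(query) - k + 1):
            hits |= self.table.get(query[i : i + k], set())
        return hits


def build_kmer_index(sequences: Iterable[str], k: int) -> KmerIndex:
    """Build a :class:`KmerIndex` over `sequences` with word size `k`."""
    return KmerIndex(sequences, k)


def find_polyT(
    seq: str,
    window: int = POLYT_WINDOW,
    min_frac_T: float = POLYT_MIN_FRAC,
    min_T: int = POLYT_MIN_T,
) -> tuple[int, int] | None:
    """Leftmost sliding window with T-fraction >= `min_frac_T`, trimmed to T
    at the edges and extended maximally; 0-based half-open, or None."""
    codes = encode(seq)
    s, e = _engine.find_polyt_window(codes, window, ceil(min_frac_T * window), min_T)
    return None if s < 0 else (int(s), int(e))


def local_align(query: str, target: str) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Smith-Waterman local alignment with +1/-1/-1 scoring.

    Returns ``(score, target_span, query_span)`` with 0-based half-open spans.
    Ties are broken toward the lowest target start, then lowest query start.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    score, qs, qe, ts, te = _engine.sw_align(encode(query), encode(target))
    return int(score), (int(ts), int(te)), (int(qs), int(qe))


@dataclass(frozen=True)
class BarcodeCall:
    """Per-read demultiplexing result; spans are on the oriented read
    (the reverse complement when ``strand_used == "reverse"``)."""

    read_id: str
    barcode: str | None
    score: int
    umi: str | None
    strand_used: str  # forward / reverse
    failure: str  # one of STAGES
    ambiguous: bool = False
    polyt_pos: tuple[int, int] | None = None
    primer_span: tuple[int, int] | None = None
    linker_span: tuple[int, int] | None = None
    barcode_span: tuple[int, int] | None = None

    @property
    def called(self) -> bool:
        return self.barcode is not None


class BarcodeCaller:
    """Whitelist-indexed caller; build once, call many reads.

    Parameters mirror the defaults of the published pipeline: whitelist k-mer
    index at k=6, primer index at k=6, linker index at k=5, minimum barcode
    alignment score 13 of a maximum 14.
    """

    def __init__(
        self,
        whitelist: Whitelist,
        layout: MoleculeLayout | None = None,
        min_score: int = 13,
        barcode_k: int = 6,
        primer_k: int = 6,
        linker_k: int = 5,
    ):
        layout = layout or MoleculeLayout()
        if layout.barcode_length != whitelist.barcode_length:
            raise ValueError(
                f"layout barcode length {layout.barcode_length} != whitelist "
                f"barcode length {whitelist.barcode_length}"
            )
        if min_score > whitelist.barcode_length:
            raise ValueError(
                f"min_score {min_score} exceeds barcode length {whitelist.barcode_length}"
            )
        self.whitelist = whitelist
        self.layout = layout
        self.min_score = int(min_score)
        self.barcode_k = barcode_k

        self._bc_codes = _engine.encode_barcodes(whitelist.barcodes)
        self._offsets, self._values = _engine.build_csr_kmer_index(self._bc_codes, barcode_k)
        self._exact = {bc: i for i, bc in enumerate(whitelist.barcodes)}
        self._exact_codes = {self._bc_codes[i].tobytes(): i for i in range(len(whitelist))}
        self._primer = encode(layout.primer_seq)
        self._linker = encode(layout.linker_seq)
        self._primer_k = primer_k
        self._linker_k = linker_k
        self._primer_table = _engine.kmer_presence_table(self._primer, primer_k)
        self._linker_table = _engine.kmer_presence_table(self._linker, linker_k)
        self._primer_min = len(layout.primer_seq) - PRIMER_SLACK
        self._linker_min = len(layout.linker_seq) - PRIMER_SLACK
        self._search_len = layout.construct_length - layout.polyt_length + SEARCH_SLACK
        # scratch buffers for candidate collection
        self._lastseen = np.full(len(whitelist), -1, dtype=np.int64)
        self._stamp = 0
        self._cand = np.empty(len(whitelist), dtype=np.int32)
        self._polyt_min_count = ceil(POLYT_MIN_FRAC * POLYT_WINDOW)

    # -- single-strand attempt ------------------------------------------------
    def _attempt(self, codes: np.ndarray):
        """Returns (stage, details) where details carry spans and the call."""
        pts, pte = _engine.find_polyt_window(
            codes, POLYT_WINDOW, self._polyt_min_count, POLYT_MIN_T
        )
        if pts < 0:
            return NO_POLYT, None
        region_start = max(0, pts - self._search_len)
        region = codes[region_start:pts]
        if not _engine.has_shared_kmer(region, self._primer_k, self._primer_table):
            return NO_PRIMER, None
        psc, _, _, p_ts, p_te = _engine.sw_align(self._primer, region)
        if psc < self._primer_min:
            return NO_PRIMER, None
        sub = region[p_te:]
        if not _engine.has_shared_kmer(sub, self._linker_k, self._linker_table):
            return NO_LINKER, None
        lsc, _, _, l_ts, l_te = _engine.sw_align(self._linker, sub)
        if lsc < self._linker_min:
            return NO_LINKER, None
        l_ts += p_te
        l_te += p_te
        bc2_len = self.layout.bc_part_lengths[1]
        part1 = region[p_te:l_ts]
        part2 = region[l_te : min(l_te + bc2_len, len(region))]
        cand_region = np.concatenate((part1, part2))
        spans = {
            "polyt": (int(pts), int(pte)),
            "primer": (int(region_start + p_ts), int(region_start + p_te)),
            "linker": (int(region_start + l_ts), int(region_start + l_te)),
            "barcode": (int(region_start + p_te), int(region_start + l_te + len(part2))),
        }
        if cand_region.shape[0] == 0:
            return LOW_SCORE, (spans, None, -1, False, region_start, l_te, pts)
        # exact shortcut: a full-length exact whitelist match scores the
        # maximum and cannot be tied by a different barcode inside the region
        if cand_region.shape[0] == self.layout.barcode_length:
            idx = self._exact_codes.get(cand_region.tobytes())
            if idx is not None:
                return OK, (spans, idx, self.layout.barcode_length, False, region_start, l_te, pts)
        self._stamp += 1
        ncand = _engine.collect_candidates(
            cand_region,
            self.barcode_k,
            self._offsets,
            self._values,
            self._lastseen,
            self._stamp,
            self._cand,
        )
        if ncand == 0:
            return LOW_SCORE, (spans, None, 0, False, region_start, l_te, pts)
        idx, score, ntop = _engine.best_barcode(self._bc_codes, self._cand, ncand, cand_region)
        ambiguous = ntop > 1
        if score < self.min_score or ambiguous:
            return LOW_SCORE, (spans, int(idx), int(score), ambiguous, region_start, l_te, pts)
        return OK, (spans, int(idx), int(score), False, region_start, l_te, pts)

    def _finish(self, read_id, strand, stage, details, codes) -> BarcodeCall:
        if details is None:
            return BarcodeCall(read_id, None, 0, None, strand, stage)
        spans, idx, score, ambiguous, region_start, l_te, pts = details
        bc2_len = self.layout.bc_part_lengths[1]
        umi_start = min(region_start + l_te + bc2_len, pts)
        umi_codes = codes[umi_start:pts]
        from ._seq import decode

        umi = decode(umi_codes) if umi_codes.shape[0] else ""
        if stage == OK:
            return BarcodeCall(
                read_id,
                self.whitelist.barcodes[idx],
                score,
                umi,
                strand,
                OK,
                False,
                spans["polyt"],
                spans["primer"],
                spans["linker"],
                spans["barcode"],
            )
        return BarcodeCall(
            read_id,
            None,
            max(score, 0),
            None,
            strand,
            stage,
            ambiguous,
            spans["polyt"],
            spans["primer"],
            spans["linker"],
            spans["barcode"],
        )

    def call(self, read_id: str, seq: str) -> BarcodeCall:
        """Call one read; tries forward, then the reverse complement."""
        codes = encode(seq)
        return self.call_encoded(read_id, codes)

    def call_encoded(self, read_id: str, codes: np.ndarray) -> BarcodeCall:
        stage_f, det_f = self._attempt(codes)
        if stage_f == OK:
            return self._finish(read_id, "forward", OK, det_f, codes)
        rc = revcomp_codes(codes)
        stage_r, det_r = self._attempt(rc)
        if stage_r == OK:
            return self._finish(read_id, "reverse", OK, det_r, rc)
        # no call on either strand: report the forward attempt's failure (the
        # read's primary orientation defines its failure mode)
        return self._finish(read_id, "forward", stage_f, det_f, codes)

    def call_all(self, reads: Iterable[tuple[str, str]]) -> Iterator[BarcodeCall]:
        for read_id, seq in reads:
            yield self.call(read_id, seq)


def call_barcode(
    read: tuple[str, str],
    whitelist: Whitelist,
    layout: MoleculeLayout | None = None,
    min_score: int = 13,
) -> BarcodeCall:
    """One-shot convenience wrapper; prefer :class:`BarcodeCaller` for batches."""
    caller = BarcodeCaller(whitelist, layout, min_score=min_score)
    return caller.call(*read)


def classify_failure(call: BarcodeCall) -> str:
    """First failing criterion in pipeline order (``ok`` when called)."""
    return call.failure


# ---------------------------------------------------------------------------
# calls TSV


CALLS_COLUMNS = (
    "read_id",
    "barcode",
    "score",
    "umi",
    "strand",
    "failure",
    "polyt",
    "primer",
    "linker",
    "barcode_span",
)


def _span_str(span: tuple[int, int] | None) -> str:
    return "." if span is None else f"{span[0]}-{span[1]}"


def write_calls(calls: Iterable[BarcodeCall], path, provenance: str | None = None) -> int:
    from .io import _open_text
    from pathlib import Path

    n = 0
    with _open_text(Path(path), "wt") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    (
                        c.read_id,
                        c.barcode or ".",
                        str(c.score),
                        c.umi if c.umi is not None else ".",
                        c.strand_used,
                        c.failure + ("_ambiguous" if c.ambiguous else ""),
                        _span_str(c.polyt_pos),
                        _span_str(c.primer_span),
                        _span_str(c.linker_span),
                        _span_str(c.barcode_span),
                    )
                )
                + "\n"
            )
            n += 1
    return n
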