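"""Read simulator and barcode-calling benchmark.

Simulated molecules follow the shared :class:`~beadsplice.layout.MoleculeLayout`:
primer + split barcode (linker in between) + UMI + 30 bp poly(T) + cDNA.
Sequencing noise is i.i.d. per base at fixed substitution/insertion/deletion
rates (defaults 1.4% / 2.0% / 1.0%, a 4.4% total error rate typical of ONT
cDNA data).  Optional read truncation removes a barcode-proximal prefix and
can delete the barcode entirely — a loss no caller can recover.  Every latent
variable is recorded in a truth table so calls can be scored exactly.

Benchmark convention: a correctly called barcode is a true positive, a wrong
barcode a false positive, and a read with no call a false negative;
precision = TP/(TP+FP), recall = TP/(TP+FP+FN) = TP/total since every
simulated read carries a true barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _engine
from ._seq import COMPLEMENT, decode, encode
from .demux import BarcodeCall, BarcodeCaller  # noqa: F401 (BarcodeCall is part of the scoring API)
from .io import TruthRecord, Whitelist, write_fastq, write_truth
from .layout import MoleculeLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. error probabilities."""

    p_sub: float = 0.014
    p_ins: float = 0.020
    p_del: float = 0.010

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name}={p} outside [0, 1)")

    @property
    def total(self) -> float:
        return self.p_sub + self.p_ins + self.p_del


NO_ERRORS = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TruncationModel:
    """Barcode-proximal prefix truncation: with probability ``p_truncate`` a
    geometric number of bases (mean ``mean_length``) is removed from the
    primer-side end of the molecule."""

    enabled: bool = True
    p_truncate: float = 0.35
    mean_length: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_truncate <= 1.0:
            raise ValueError("p_truncate outside [0, 1]")
        if self.mean_length < 1.0:
            raise ValueError("mean_length must be >= 1")


NO_TRUNCATION = TruncationModel(enabled=False)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the benchmark design: ~70,000 distinct whitelist barcodes,
    9 bp UMIs with the last two bases non-T, 30 bp poly(T), random reference
    transcripts with log-normal expression, reads flipped to either strand
    with probability 0.5.
    """

    n_molecules: int = 10_000
    n_reads: int | None = None  # defaults to n_molecules (no PCR duplication)
    n_barcodes: int = 70_000
    whitelist: Whitelist | None = None
    layout: MoleculeLayout = field(default_factory=MoleculeLayout)
    errors: ErrorModel = field(default_factory=ErrorModel)
    truncation: TruncationModel = field(default_factory=TruncationModel)
    strand_flip_prob: float = 0.5
    n_transcripts: int = 500
    transcript_log_mean: float = 6.2  # median length ~490 bases
    transcript_log_sigma: float = 0.4
    transcript_min_len: int = 150
    transcript_max_len: int = 4000
    transcripts: Sequence[str] | None = None  # overrides synthetic generation
    expression: str = "log-normal"  # or "uniform"
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads is None:
            self.n_reads = self.n_molecules
        if self.n_reads < self.n_molecules and self.n_reads > 0:
            raise ValueError("n_reads must be >= n_molecules (each molecule is read >= 1x)")
        if not 0.0 <= self.strand_flip_prob <= 1.0:
            raise ValueError("strand_flip_prob outside [0, 1]")
        if self.expression not in ("log-normal", "uniform"):
            raise ValueError(f"unknown expression model {self.expression!r}")


def make_whitelist(n: int, length: int = 14, rng: np.random.Generator | None = None) -> Whitelist:
    """`n` distinct uniform random barcodes of the given length."""
    rng = rng or np.random.default_rng()
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    keys: np.ndarray = np.empty(0, dtype=np.uint64)
    while keys.size < n:
        draw = rng.integers(0, 4**length, size=max(n - keys.size, n // 4 + 4), dtype=np.uint64)
        keys = np.unique(np.concatenate([keys, draw]))
    # np.unique sorts; shuffle so the list order carries no structure
    rng.shuffle(keys)
    keys = keys[:n]
    codes = np.empty((n, length), dtype=np.uint8)
    for j in range(length):
        codes[:, length - 1 - j] = (keys >> np.uint64(2 * j)) & np.uint64(3)
    return Whitelist(tuple(decode(row) for row in codes))


def sample_umi(rng: np.random.Generator, length: int = 9) -> str:
    """Uniform UMI of the given length whose last two bases are not T."""
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    codes[-2:] = rng.integers(0, 3, size=2).astype(np.uint8)
    return decode(codes)


def umi_space_size(length: int = 9) -> int:
    """Number of distinct UMIs under the last-two-non-T constraint."""
    if length < 2:
        raise ValueError("UMI length must be >= 2")
    return 4 ** (length - 2) * 3 * 3


def make_molecule(transcript: str, barcode: str, umi: str, layout: MoleculeLayout) -> str:
    """Deterministic molecule assembly in layout order, barcode split around
    the linker; the cDNA is the reverse complement of the transcript (the
    barcode strand is the first cDNA strand, primed at the poly(A) tail)."""
    if len(barcode) != layout.barcode_length:
        raise ValueError(
            f"barcode length {len(barcode)} != layout barcode length {layout.barcode_length}"
        )
    p1 = layout.bc_part_lengths[0]
    from ._seq import revcomp

    return (
        layout.primer_seq
        + barcode[:p1]
        + layout.linker_seq
        + barcode[p1:]
        + umi
        + "T" * layout.polyt_length
        + revcomp(transcript)
    )


@dataclass(frozen=True)
class EditLog:
    """Positions (on the input sequence) of injected errors."""

    n_sub: int
    n_ins: int
    n_del: int
    ops: tuple[tuple[int, str], ...] = ()


def _inject_codes(
    codes: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, int, int]]:
    n = codes.shape[0]
    if n == 0 or model.total == 0.0:
        return codes, (0, 0, 0)
    rand = rng.random(2 * n)
    bases = rng.integers(0, 4, size=2 * n).astype(np.uint8)
    out = np.empty(2 * n + 1, dtype=np.uint8)
    ln, ns, ni, nd = _engine.inject_errors_flat(
        codes, model.p_sub, model.p_ins, model.p_del, rand, bases, out
    )
    return out[:ln].copy(), (int(ns), int(ni), int(nd))


def inject_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator, with_log: bool = False
) -> tuple[str, EditLog]:
    """Apply the i.i.d. error process to one sequence.

    With ``with_log`` the returned :class:`EditLog` carries per-position ops
    ``(input_position, op)`` with op in {"sub", "ins", "del"}; an insertion at
    position i is placed after base i.
    """
    codes = encode(seq)
    n = codes.shape[0]
    if n == 0 or model.total == 0.0:
        return seq, EditLog(0, 0, 0)
    rand = rng.random(2 * n)
    bases = rng.integers(0, 4, size=2 * n).astype(np.uint8)
    out: list[int] = []
    ops: list[tuple[int, str]] = []
    for i in range(n):
        u = rand[2 * i]
        c = int(codes[i])
        if u < model.p_del:
            ops.append((i, "del"))
        elif u < model.p_del + model.p_sub:
            out.append((c + 1 + int(bases[2 * i]) % 3) % 4)
            ops.append((i, "sub"))
        else:
            out.append(c)
        if rand[2 * i + 1] < model.p_ins:
            out.append(int(bases[2 * i + 1]))
            ops.append((i, "ins"))
    ns = sum(1 for _, op in ops if op == "sub")
    ni = sum(1 for _, op in ops if op == "ins")
    nd = sum(1 for _, op in ops if op == "del")
    log = EditLog(ns, ni, nd, tuple(ops) if with_log else ())
    return decode(np.array(out, dtype=np.uint8)), log


@dataclass
class SimulatedDataset:
    """In-memory simulated reads plus their truth table."""

    read_ids: list[str]
    sequences: list[np.ndarray]  # encoded uint8 arrays
    truth: list[TruthRecord]
    whitelist: Whitelist
    layout: MoleculeLayout
    config: SimConfig

    def __len__(self) -> int:
        return len(self.read_ids)

    def iter_reads(self) -> Iterator[tuple[str, str]]:
        for rid, codes in zip(self.read_ids, self.sequences):
            yield rid, decode(codes)

    def write_fastq(self, path) -> int:
        return write_fastq(self.iter_reads(), path)

    def write_truth(self, path) -> int:
        return write_truth(self.truth, path)


def synthetic_transcripts(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lengths = np.clip(
        rng.lognormal(cfg.transcript_log_mean, cfg.transcript_log_sigma, cfg.n_transcripts),
        cfg.transcript_min_len,
        cfg.transcript_max_len,
    ).astype(np.int64)
    return [rng.integers(0, 4, size=int(L)).astype(np.uint8) for L in lengths]


def simulate_dataset(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate reads with known truth under the configured study conditions."""
    rng = rng or np.random.default_rng(cfg.seed)
    layout = cfg.layout
    whitelist = cfg.whitelist or make_whitelist(cfg.n_barcodes, layout.barcode_length, rng)
    if cfg.n_reads == 0 or cfg.n_molecules == 0:
        return SimulatedDataset([], [], [], whitelist, layout, cfg)

    if cfg.transcripts is not None:
        # cDNA strand: reverse complement of the provided transcript sense
        transcripts = [COMPLEMENT[encode(t)[::-1]] for t in cfg.transcripts]
    else:
        transcripts = synthetic_transcripts(cfg, rng)
    ntx = len(transcripts)
    if cfg.expression == "log-normal":
        w = rng.lognormal(0.0, cfg.expression_sigma, ntx)
        w /= w.sum()
    else:
        w = np.full(ntx, 1.0 / ntx)

    n_mol = cfg.n_molecules
    tx_idx = rng.choice(ntx, size=n_mol, p=w)
    bc_idx = rng.integers(0, len(whitelist), size=n_mol)
    umi_codes = rng.integers(0, 4, size=(n_mol, layout.umi_length)).astype(np.uint8)
    umi_codes[:, -2:] = rng.integers(0, 3, size=(n_mol, 2)).astype(np.uint8)

    bc_codes = _engine.encode_barcodes(whitelist.barcodes)
    primer = encode(layout.primer_seq)
    linker = encode(layout.linker_seq)
    polyt = np.full(layout.polyt_length, 3, dtype=np.uint8)
    p1 = layout.bc_part_lengths[0]
    primer_len = len(layout.primer_seq)

    # read -> molecule map; molecules beyond the first n_molecules are PCR copies
    n_reads = int(cfg.n_reads)
    mol_of_read = np.arange(n_reads, dtype=np.int64)
    if n_reads > n_mol:
        mol_of_read[n_mol:] = rng.integers(0, n_mol, size=n_reads - n_mol)
        rng.shuffle(mol_of_read)
    else:
        mol_of_read = mol_of_read[:n_reads]

    flip = rng.random(n_reads) < cfg.strand_flip_prob
    if cfg.truncation.enabled:
        truncate = rng.random(n_reads) < cfg.truncation.p_truncate
        trunc_len = rng.geometric(1.0 / cfg.truncation.mean_length, size=n_reads)
    else:
        truncate = np.zeros(n_reads, dtype=bool)
        trunc_len = np.zeros(n_reads, dtype=np.int64)

    read_ids: list[str] = []
    seqs: list[np.ndarray] = []
    truth: list[TruthRecord] = []
    width = len(str(max(n_reads - 1, 1)))
    for r in range(n_reads):
        m = int(mol_of_read[r])
        bc = bc_codes[bc_idx[m]]
        molecule = np.concatenate(
            (primer, bc[:p1], linker, bc[p1:], umi_codes[m], polyt, transcripts[tx_idx[m]])
        )
        tl = int(trunc_len[r]) if truncate[r] else 0
        if tl > 0:
            molecule = molecule[tl:]
        if flip[r]:
            molecule = COMPLEMENT[molecule[::-1]]
        read, _ = _inject_codes(molecule, cfg.errors, rng)
        rid = f"sim_{r:0{width}d}"
        read_ids.append(rid)
        seqs.append(read)
        truth.append(
            TruthRecord(
                read_id=rid,
                true_barcode=whitelist.barcodes[int(bc_idx[m])],
                true_umi=decode(umi_codes[m]),
                transcript_id=f"tx_{int(tx_idx[m])}",
                truncated=bool(truncate[r] and tl > 0),
                strand_flipped=bool(flip[r]),
                barcode_intact=tl <= primer_len,
            )
        )
    return SimulatedDataset(read_ids, seqs, truth, whitelist, layout, cfg)


# ---------------------------------------------------------------------------
# benchmark scoring


@dataclass(frozen=True)
class BenchmarkResult:
    """Confusion counts for barcode calls at one score threshold."""

    score_threshold: int
    tp: int
    fp: int
    fn: int
    per_barcode: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        total = self.tp + self.fp + self.fn
        return 0.0 if total == 0 else self.tp / total

    def per_barcode_precision(self) -> dict[str, float]:
        return {
            bc: tp / (tp + fp) for bc, (tp, fp) in self.per_barcode.items() if tp + fp > 0
        }


def evaluate_calls(
    calls: Iterable[BarcodeCall],
    truth: Iterable[TruthRecord],
    score_threshold: int | None = None,
    per_barcode: bool = False,
) -> BenchmarkResult:
    """Score calls against simulation truth.

    The read_id join must be total: every call needs a truth record and every
    truth record a call.  With ``score_threshold`` set, calls below it are
    treated as no-calls (re-thresholding without re-running the caller).
    """
    truth_by_id = {t.read_id: t for t in truth}
    tp = fp = 0
    n_seen = 0
    pb: dict[str, list[int]] = {}
    for c in calls:
        t = truth_by_id.get(c.read_id)
        if t is None:
            raise ValueError(f"call for unknown read {c.read_id!r}")
        n_seen += 1
        called = c.called and (score_threshold is None or c.score >= score_threshold)
        if not called:
            continue
        if c.barcode == t.true_barcode:
            tp += 1
            if per_barcode:
                pb.setdefault(c.barcode, [0, 0])[0] += 1
        else:
            fp += 1
            if per_barcode:
                pb.setdefault(c.barcode, [0, 0])[1] += 1
    if n_seen != len(truth_by_id):
        raise ValueError(f"{len(truth_by_id) - n_seen} truth reads have no call record")
    fn = n_seen - tp - fp
    return BenchmarkResult(
        score_threshold if score_threshold is not None else -1,
        tp,
        fp,
        fn,
        {bc: (v[0], v[1]) for bc, v in pb.items()},
    )


def sweep_thresholds(
    calls: Sequence[BarcodeCall],
    truth: Sequence[TruthRecord],
    thresholds: Sequence[int] = (11, 12, 13, 14),
) -> list[BenchmarkResult]:
    """Precision/recall at several minimal scores from one set of calls.

    The calls must have been made at ``min_score <= min(thresholds)``.
    """
    return [evaluate_calls(calls, truth, score_threshold=t) for t in thresholds]


def run_benchmark(
    dataset: SimulatedDataset,
    min_score: int = 11,
    thresholds: Sequence[int] = (11, 12, 13, 14),
    caller: BarcodeCaller | None = None,
) -> tuple[list[BarcodeCall], list[BenchmarkResult]]:
    """Call every simulated read and score it at each threshold."""
    caller = caller or BarcodeCaller(dataset.whitelist, dataset.layout, min_score=min_score)
    calls = [caller.call_encoded(rid, codes) for rid, codes in zip(dataset.read_ids, dataset.sequences)]
    return calls, sweep_thresholds(calls, dataset.truth, thresholds)


# ---------------------------------------------------------------------------
# AllInfo-level generators
#
# The statistical stages consume read models (gene, group, intron chain,
# poly(A) site ...) produced upstream of this package by genome alignment.
# These generators emulate that upstream output directly, with known
# inclusion/usage truth, so the testing stages can be validated at the level
# they operate on.


def _gene_structure(g: int, cassette_len: int = 150) -> dict:
    """Deterministic 3-exon gene model for synthetic gene `g`: two flanking
    exons and a cassette exon in between."""
    o = 10_000 * (g + 1)
    chrom = f"chr{1 + g % 5}"
    strand = "+" if g % 2 == 0 else "-"
    e1 = (o + 1, o + 300)
    cas = (o + 500, o + 499 + cassette_len)
    e3 = (o + 800, o + 1200)
    return {"chrom": chrom, "strand": strand, "e1": e1, "cassette": cas, "e3": e3}


def cassette_read(
    gene: str,
    g: int,
    read_id: str,
    group: str,
    barcode: str,
    umi: str,
    included: bool,
) -> "ReadModel":
    """One spliced read over the synthetic 3-exon gene, including or skipping
    the cassette exon."""
    from .io import ReadModel

    st = _gene_structure(g)
    e1, cas, e3 = st["e1"], st["cassette"], st["e3"]
    if included:
        blocks = (e1, cas, e3)
        introns = ((e1[1] + 1, cas[0] - 1), (cas[1] + 1, e3[0] - 1))
    else:
        blocks = (e1, e3)
        introns = ((e1[1] + 1, e3[0] - 1),)
    return ReadModel(
        read_id=read_id,
        gene_id=gene,
        group=group,
        barcode=barcode,
        umi=umi,
        intron_chain=introns,
        exon_blocks=blocks,
        chrom=st["chrom"],
        strand=st["strand"],
        tss=blocks[0][0] if st["strand"] == "+" else blocks[-1][1],
        polya=blocks[-1][1] if st["strand"] == "+" else blocks[0][0],
    )


def simulate_cassette_read_models(
    n_genes: int,
    reads_per_group: int,
    psi_g1,
    psi_g2,
    rng: np.random.Generator,
    groups: tuple[str, str] = ("g1", "g2"),
) -> list:
    """Two-group spliced reads over synthetic cassette-exon genes.

    ``psi_g1``/``psi_g2`` are scalars or per-gene arrays of true inclusion
    rates; inclusion is drawn per read (binomial sampling).  Every read gets
    a unique UMI/barcode pairing so deduplication is the identity.
    """
    psi_g1 = np.broadcast_to(np.asarray(psi_g1, dtype=float), (n_genes,))
    psi_g2 = np.broadcast_to(np.asarray(psi_g2, dtype=float), (n_genes,))
    out = []
    counter = 0
    for g in range(n_genes):
        gene = f"gene_{g:05d}"
        for group, psi in zip(groups, (psi_g1[g], psi_g2[g])):
            incl = rng.random(reads_per_group) < psi
            for k in range(reads_per_group):
                rid = f"r{counter:08d}"
                counter += 1
                out.append(
                    cassette_read(
                        gene, g, rid, group,
                        barcode=f"BC{counter % 97:03d}",
                        umi=f"U{counter:08d}",
                        included=bool(incl[k]),
                    )
                )
    return out


def simulate_usage_read_models(
    n_genes: int,
    reads_per_group: int,
    probs_g1,
    probs_g2,
    rng: np.random.Generator,
    groups: tuple[str, str] = ("g1", "g2"),
) -> list:
    """Two-group unspliced reads with per-gene multinomial poly(A)-site usage.

    ``probs_g1``/``probs_g2`` are category-probability vectors (shared across
    genes) or (n_genes, K) arrays.  Site k of gene g sits at a distinct
    genomic coordinate so usage tables rank real positions.
    """
    from .io import ReadModel

    probs_g1 = np.asarray(probs_g1, dtype=float)
    probs_g2 = np.asarray(probs_g2, dtype=float)
    if probs_g1.ndim == 1:
        probs_g1 = np.broadcast_to(probs_g1, (n_genes, probs_g1.size))
    if probs_g2.ndim == 1:
        probs_g2 = np.broadcast_to(probs_g2, (n_genes, probs_g2.size))
    out = []
    counter = 0
    for g in range(n_genes):
        gene = f"gene_{g:05d}"
        o = 10_000 * (g + 1)
        for group, probs in zip(groups, (probs_g1[g], probs_g2[g])):
            sites = rng.choice(probs.size, size=reads_per_group, p=probs / probs.sum())
            for k in range(reads_per_group):
                rid = f"r{counter:08d}"
                counter += 1
                polya = o + 500 + 200 * int(sites[k])
                out.append(
                    ReadModel(
                        read_id=rid,
                        gene_id=gene,
                        group=group,
                        barcode=f"BC{counter % 97:03d}",
                        umi=f"U{counter:08d}",
                        intron_chain=(),
                        exon_blocks=((o + 1, polya),),
                        chrom=f"chr{1 + g % 5}",
                        strand="+",
                        polya=polya,
                    )
                )
    return out
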