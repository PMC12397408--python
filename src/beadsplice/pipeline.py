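"""End-to-end pipeline: simulate -> demux -> annotate -> dedup -> exon tests.

The full production pipeline maps barcoded reads to a genome and assigns them
to genes before deduplication; genome alignment is outside this package, so
the ``run-all`` orchestration replaces that stage with an *annotate* step
that joins calls with simulation truth (gene = source transcript) and
attaches a synthetic cassette-exon structure with a known per-gene inclusion
rate per group.  This exercises every stage the package owns on data whose
answer is known.

Every stage reports reads in/out; outputs carry a provenance header with the
tool version, a config hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dedup import DedupStats, dedup_all
from .demux import BarcodeCaller, write_calls
from .exons import run_exon_tests, summarize, write_exon_results
from .io import write_allinfo
from .sim import (
    ErrorModel,
    SimConfig,
    TruncationModel,
    cassette_read,
    evaluate_calls,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One human-readable configuration for the whole run."""

    n_molecules: int = 2000
    n_reads: int | None = None
    n_barcodes: int = 5000
    min_score: int = 13
    seed: int = 0
    p_sub: float = 0.014
    p_ins: float = 0.020
    p_del: float = 0.010
    truncation: bool = True
    p_truncate: float = 0.35
    truncation_mean_length: float = 300.0
    n_genes: int = 20
    psi_g1: float = 0.5
    psi_g2: float = 0.5
    min_reads: int = 10
    out_dir: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"beadsplice {__version__} config={self.config_hash()} seed={self.seed}"


def _stable_unit(key: str) -> float:
    """Deterministic pseudo-uniform in [0, 1) from a string key."""
    return (zlib.crc32(key.encode()) & 0xFFFFFFFF) / 2**32


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a machine-readable result bundle."""
    report: dict = {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: %d molecules", cfg.n_molecules)
    sim_cfg = SimConfig(
        n_molecules=cfg.n_molecules,
        n_reads=cfg.n_reads,
        n_barcodes=cfg.n_barcodes,
        errors=ErrorModel(cfg.p_sub, cfg.p_ins, cfg.p_del),
        truncation=TruncationModel(
            enabled=cfg.truncation,
            p_truncate=cfg.p_truncate,
            mean_length=cfg.truncation_mean_length,
        ),
        seed=cfg.seed,
    )
    dataset = simulate_dataset(sim_cfg)
    report["simulate"] = {"reads": len(dataset)}
    if out_dir:
        dataset.write_fastq(out_dir / "reads.fastq")
        dataset.write_truth(out_dir / "truth.tsv")

    logger.info("stage demux: %d reads", len(dataset))
    caller = BarcodeCaller(dataset.whitelist, dataset.layout, min_score=cfg.min_score)
    calls = [
        caller.call_encoded(rid, codes)
        for rid, codes in zip(dataset.read_ids, dataset.sequences)
    ]
    bench = evaluate_calls(calls, dataset.truth, per_barcode=False)
    report["demux"] = {
        "reads_in": len(calls),
        "called": bench.tp + bench.fp,
        "precision": bench.precision,
        "recall": bench.recall,
    }
    if out_dir:
        write_calls(calls, out_dir / "calls.tsv", provenance=cfg.provenance())

    # annotate: join calls with truth; synthetic per-gene cassette structure
    truth_by_id = {t.read_id: t for t in dataset.truth}
    rng = np.random.default_rng(cfg.seed + 1)
    gene_psi = {
        f"gene_{g:05d}": (cfg.psi_g1, cfg.psi_g2) for g in range(cfg.n_genes)
    }
    records = []
    for c in calls:
        if not c.called:
            continue
        t = truth_by_id[c.read_id]
        g = int(t.transcript_id.split("_")[1]) % cfg.n_genes
        gene = f"gene_{g:05d}"
        group = "G1" if _stable_unit("grp:" + t.true_barcode) < 0.5 else "G2"
        psi = gene_psi[gene][0 if group == "G1" else 1]
        # inclusion is a property of the molecule, not the read copy
        included = _stable_unit(f"iso:{t.true_barcode}:{t.true_umi}:{t.transcript_id}") < psi
        records.append(
            cassette_read(
                gene, g, c.read_id, group,
                barcode=c.barcode, umi=c.umi or t.true_umi, included=included,
            )
        )
    report["annotate"] = {"reads": len(records)}

    logger.info("stage dedup: %d records", len(records))
    stats = DedupStats()
    deduped = list(dedup_all(records, stats=stats))
    report["dedup"] = {
        "reads_in": stats.n_reads,
        "reads_out": stats.n_kept,
        "duplicates_removed": stats.n_duplicates,
    }
    if out_dir:
        write_allinfo(deduped, out_dir / "allinfo.tsv", provenance=cfg.provenance())

    logger.info("stage exon tests: %d records", len(deduped))
    results = run_exon_tests(deduped, "G1", "G2", min_reads=cfg.min_reads)
    summ = summarize(results)
    report["exon_tests"] = {
        "candidates": summ.n_candidates,
        "tested": summ.n_tested,
        "significant": summ.n_significant,
        "percent_significant": summ.percent_significant,
    }
    if out_dir:
        write_exon_results(results, out_dir / "exon_tests.tsv", provenance=cfg.provenance())
        (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    # conservation audit: read counts never grow through demux -> dedup
    assert report["demux"]["called"] <= report["simulate"]["reads"]
    assert report["dedup"]["reads_out"] <= report["dedup"]["reads_in"]
    return report
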