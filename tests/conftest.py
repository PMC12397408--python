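import numpy as np
import pytest

from beadsplice.io import ReadModel, Whitelist
from beadsplice.layout import MoleculeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout():
    return MoleculeLayout()


@pytest.fixture
def small_whitelist(rng):
    from beadsplice.sim import make_whitelist

    return make_whitelist(500, 14, rng)


def make_read(
    read_id="r1",
    gene="geneA",
    group="g1",
    blocks=((100, 200), (500, 900)),
    chrom="chr1",
    strand="+",
    barcode="ACGTACGTACGTAA",
    umi="ACGTACGTA",
    tss=None,
    polya=None,
    novelty="known",
):
    """ReadModel with introns derived from the gaps between exon blocks."""
    introns = tuple(
        (blocks[i][1] + 1, blocks[i + 1][0] - 1) for i in range(len(blocks) - 1)
    )
    return ReadModel(
        read_id=read_id,
        gene_id=gene,
        group=group,
        barcode=barcode,
        umi=umi,
        intron_chain=introns,
        exon_blocks=tuple(blocks),
        chrom=chrom,
        strand=strand,
        tss=tss,
        polya=polya,
        novelty=novelty,
    )
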