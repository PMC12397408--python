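"""Declarative description of the barcoded molecule structure.

A spatial cDNA molecule reads, 5' to 3' on the barcode strand::

    primer | barcode part 1 | linker | barcode part 2 | UMI | polyT | cDNA

The bead barcode (14 bp on Curio-style slides) is split into two parts by a
fixed linker.  The same :class:`MoleculeLayout` instance is shared by the read
simulator and the barcode caller, so benchmarks are self-consistent by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# UPS amplification primer used to amplify spliced cDNA in this chemistry.
DEFAULT_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"
# Slide-seq-lineage split-barcode linker; slide vendors do not publish it, so
# it is configurable and this default is only a documented convention.
DEFAULT_LINKER = "TCTTCAGCGTTCCCGAGA"


@dataclass(frozen=True)
class MoleculeLayout:
    """Barcoded read structure shared by simulator and caller.

    Parameters
    ----------
    primer_seq : str
        Amplification primer preceding the barcode.
    linker_seq : str
        Fixed sequence splitting the barcode into two parts.
    bc_part_lengths : tuple[int, int]
        Lengths of the two barcode parts (default 8 + 6 = 14).
    umi_length : int
        Nominal unique-molecular-identifier length (default 9).
    polyt_length : int
        Length of the poly(T) stretch written by the simulator (default 30).
    """

    primer_seq: str = DEFAULT_PRIMER
    linker_seq: str = DEFAULT_LINKER
    bc_part_lengths: tuple[int, int] = (8, 6)
    umi_length: int = 9
    polyt_length: int = 30

    def __post_init__(self) -> None:
        if len(self.bc_part_lengths) != 2 or min(self.bc_part_lengths) < 1:
            raise ValueError("bc_part_lengths must be two positive integers")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.polyt_length < 10:
            raise ValueError("polyt_length must be >= 10")
        for name in ("primer_seq", "linker_seq"):
            s = getattr(self, name)
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")

    @property
    def barcode_length(self) -> int:
        return sum(self.bc_part_lengths)

    @property
    def construct_length(self) -> int:
        """Length of the non-cDNA portion of the molecule (primer..polyT)."""
        return (
            len(self.primer_seq)
            + self.barcode_length
            + len(self.linker_seq)
            + self.umi_length
            + self.polyt_length
        )
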