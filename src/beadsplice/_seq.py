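"""Nucleotide sequence encoding helpers shared by the fast engine and the simulator.

Sequences are held as ``uint8`` arrays with A=0, C=1, G=2, T=3; any other
character maps to 4 (never matches anything).
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
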