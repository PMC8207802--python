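"""Standard genetic code and small nucleotide utilities shared by the
simulator and the variant annotator."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_CODON_STRING = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
# index = a*16 + c*4 + g with A,C,G,T -> 0..3


def codon_index(c0: int, c1: int, c2: int) -> int:
    return (c0 << 4) | (c1 << 2) | c2


AA_BY_CODON_INDEX = np.frombuffer(_CODON_STRING.encode(), dtype="S1")

CODON_TABLE = {
    a + b + c: AA_BY_CODON_INDEX[
        codon_index(BASE_CODE[a], BASE_CODE[b], BASE_CODE[c])
    ].decode()
    for a in BASES
    for b in BASES
    for c in BASES
}

STOP_CODONS = tuple(c for c, aa in CODON_TABLE.items() if aa == "*")


def translate(seq: str) -> str:
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in BASE_CODE.items():
        out[arr == ord(base)] = code
    if np.any(out == 255):
        raise ValueError("non-ACGT character in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode()
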