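"""Shared 4-mer end-motif alphabet and sequence encoding helpers.

cfDNA end motifs are the first four bases at the 5' end of each strand of a
plasma DNA molecule. All 256 motifs are indexed lexicographically
(AAAA=0 ... TTTT=255) throughout the package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
MOTIF_K = 4
N_MOTIFS = 4**MOTIF_K

#: All 256 4-mers in lexicographic order.
MOTIFS: list[str] = [
    a + b + c + d for a in BASES for b in BASES for c in BASES for d in BASES
]
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# byte-value -> base code (A=0, C=1, G=2, T=3), 255 for anything else (N etc.)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes; non-ACGT bases become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[codes == i] = ord(b)
    return out.tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray) -> np.ndarray:
    """4-mer code at every start position of an encoded sequence.

    Returns an int32 array of length ``len(codes) - 3``; positions whose
    window contains a non-ACGT base get code -1.
    """
    c = codes.astype(np.int32)
    k4 = ((c[:-3] * 4 + c[1:-2]) * 4 + c[2:-1]) * 4 + c[3:]
    bad = (c[:-3] > 3) | (c[1:-2] > 3) | (c[2:-1] > 3) | (c[3:] > 3)
    k4[bad] = -1
    return k4


def motif_code(motif: str) -> int:
    return MOTIF_INDEX[motif.upper()]


def decode_motif(code: int) -> str:
    return MOTIFS[code]


def revcomp_code(code: int) -> int:
    """Motif code of the reverse complement of the motif with this code."""
    digits = [(code >> (2 * i)) & 3 for i in range(4)]  # last base first
    return sum((3 - d) << (2 * (3 - i)) for i, d in enumerate(digits))


#: vectorised lookup table: REVCOMP_CODE[m] = code of revcomp(motif m)
REVCOMP_CODE = np.array([revcomp_code(m) for m in range(N_MOTIFS)], dtype=np.int32)
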