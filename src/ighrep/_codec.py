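"""Nucleotide/amino-acid encoding and fast vectorised translation.

Bases are encoded A,C,G,T -> 0..3 (anything else, e.g. N, -> 4); amino acids
are indexed into the 20-letter alphabet with X (unknown) = 20 and * (stop)
= 21.  The codon table is built once from Biopython's standard table so the
numpy translation path cannot drift from the canonical genetic code.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_X = 20
AA_STOP = 21
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
AA_INDEX["X"] = AA_X
AA_INDEX["*"] = AA_STOP
AA_LETTERS = AA_ALPHABET + "X*"

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i

# codon index = 16*b0 + 4*b1 + b2 ; codons touching a non-ACGT base -> X
_CODON_AA = np.empty(64, dtype=np.uint8)
for _c in range(64):
    _codon = "ACGT"[_c >> 4] + "ACGT"[(_c >> 2) & 3] + "ACGT"[_c & 3]
    _CODON_AA[_c] = AA_INDEX[str(Seq(_codon).translate())]


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (non-ACGT -> 4)."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate_codes(codes: np.ndarray, frame: int = 0) -> np.ndarray:
    """Translate encoded nucleotides to encoded amino acids (frame-shifted).

    Trailing incomplete codons are dropped; codons containing an ambiguous
    base translate to X.
    """
    c = codes[frame:]
    n = len(c) // 3
    c = c[: 3 * n].reshape(n, 3).astype(np.int64)
    bad = (c >= 4).any(axis=1)
    idx = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
    idx[bad] = 0
    aa = _CODON_AA[idx].copy()
    aa[bad] = AA_X
    return aa


def translate(seq: str, frame: int = 0) -> str:
    """Translate a nucleotide string; returns one-letter amino acids."""
    return decode_aa(translate_codes(encode_nt(seq), frame))


def decode_aa(aa_codes: np.ndarray) -> str:
    return "".join(AA_LETTERS[i] for i in aa_codes)


def encode_aa(aa: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, AA_X) for ch in aa], dtype=np.uint8)
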