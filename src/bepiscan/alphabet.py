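"""The 20-letter amino-acid alphabet, integer encoding, and BLOSUM62 access.

Everything downstream (composition statistics, BLOSUM62 scoring, the
ungapped search engine) is defined on the 20 standard residues; records
containing other letters (B, J, O, U, X, Z, ...) are rejected at the
dataset boundary, not here.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Standard amino acids in the conventional alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_SET = frozenset(AMINO_ACIDS)

#: residue letter -> code in 0..19
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# ord-indexed lookup table; 255 marks a non-standard byte
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_aa)] = _i


def is_valid_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and uses only the 20 standard residues."""
    return bool(seq) and AA_SET.issuperset(seq)


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as a uint8 array of codes in 0..19.

    Raises ``ValueError`` on characters outside the standard alphabet.
    """
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size == 0 or (arr == 255).any():
        bad = sorted(set(seq) - AA_SET)
        raise ValueError(f"sequence contains non-standard residues: {bad!r}")
    return arr


def _build_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = int(mat[a, b])
    return out


#: BLOSUM62 as a dense 20x20 integer array indexed by ``AA_INDEX`` codes.
BLOSUM62: np.ndarray = _build_blosum62()


def blosum62_score(a: str, b: str) -> int:
    """Substitution score for a single residue pair."""
    return int(BLOSUM62[AA_INDEX[a], AA_INDEX[b]])
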