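"""Amino-acid alphabet and state encoding.

The Potts machinery works over 21 states: the 20 standard amino acids
(alphabetical one-letter order) plus a final catch-all state for gaps and
non-standard residue codes (X, B, Z, ...).  Coupling-score (Frobenius norm)
computations use only the 20 amino-acid states.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
GAP_STATE = 20
N_STATES = 21

#: characters treated as null (gap) in alignments
NULL_CHARS = frozenset("-.")

_CHAR_TO_STATE = np.full(128, GAP_STATE, dtype=np.int8)
for _i, _c in enumerate(AMINO_ACIDS):
    _CHAR_TO_STATE[ord(_c)] = _i
    _CHAR_TO_STATE[ord(_c.lower())] = _i

# encoding used for identity computations: nulls -> -1, so that a
# null never matches anything (including another null)
_CHAR_TO_IDENT = _CHAR_TO_STATE.copy()
for _c in NULL_CHARS:
    _CHAR_TO_IDENT[ord(_c)] = -1


def encode_states(rows: np.ndarray) -> np.ndarray:
    """Map a byte matrix of alignment characters to Potts states 0..20."""
    return _CHAR_TO_STATE[rows]


def encode_identity(rows: np.ndarray) -> np.ndarray:
    """Map characters to states with nulls as -1 (for identity counts)."""
    return _CHAR_TO_IDENT[rows]


def rows_to_bytes(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequence strings into a (n, width) uint8 matrix."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1).copy()


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
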