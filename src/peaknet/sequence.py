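"""One-hot encoding and decoding of DNA sequences.

Rows are indexed A, C, G, T.  An ambiguous N contributes 0.25 to every
row so columns always sum to one; any other character is rejected.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def one_hot_encode(seq: str, dtype=np.float32) -> np.ndarray:
    """Encode a DNA string as a 4 x L matrix with columns summing to 1.

    Case-insensitive over the alphabet {A, C, G, T, N}; raises
    ``ValueError`` naming the first offending position otherwise.
    """
    seq = seq.upper()
    mat = np.zeros((4, len(seq)), dtype=dtype)
    for pos, base in enumerate(seq):
        idx = BASE_INDEX.get(base)
        if idx is not None:
            mat[idx, pos] = 1.0
        elif base == "N":
            mat[:, pos] = 0.25
        else:
            raise ValueError(f"invalid base {base!r} at position {pos}")
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for unambiguous columns.

    Columns without a dominant row (e.g. the uniform N encoding) decode
    to 'N'.
    """
    matrix = np.asarray(matrix)
    out = []
    for col in matrix.T:
        top = int(np.argmax(col))
        out.append(BASES[top] if col[top] > 0.5 else "N")
    return "".join(out)


def encode_batch(seqs, dtype=np.float32) -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into (N, 4, L)."""
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, 4, 0), dtype=dtype)
    length = len(seqs[0])
    out = np.zeros((len(seqs), 4, length), dtype=dtype)
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError("sequences must share one length")
        out[i] = one_hot_encode(s, dtype=dtype)
    return out


def encode_indices(idx: np.ndarray, dtype=np.float32) -> np.ndarray:
    """One-hot encode integer base indices (N, L) with values in 0..3."""
    idx = np.asarray(idx)
    eye = np.eye(4, dtype=dtype)
    return np.ascontiguousarray(eye[idx].transpose(0, 2, 1))
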