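"""Integer encoding of DNA sequences and k-mers.

Bases are encoded A=0, C=1, G=2, T=3.  A k-mer maps to its lexicographic
index in base 4 with the first (5'-most) base most significant, so the
4^k k-mers in index order are AAAA..A, AAAA..C, ..., TTTT..T.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int64 code array.

    Raises ValueError on any non-ACGT character (no IUPAC expansion).
    """
    try:
        return np.array([_BASE_TO_CODE[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in np.asarray(codes))


def kmer_index(codes: np.ndarray) -> int:
    """Lexicographic index of a single k-mer code array."""
    idx = 0
    for c in np.asarray(codes):
        idx = idx * 4 + int(c)
    return idx


def all_kmer_codes(k: int) -> np.ndarray:
    """(4^k, k) int8 matrix of all k-mers in lexicographic order."""
    if k == 0:
        return np.empty((1, 0), dtype=np.int8)
    n = 4**k
    idx = np.arange(n)
    cols = [(idx >> (2 * (k - 1 - j))) & 3 for j in range(k)]
    return np.stack(cols, axis=1).astype(np.int8)


def windows_to_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Indices of all length-k windows of a code matrix.

    ``codes`` is (n, L) (or (L,)); returns (n, L-k+1) int64 window indices.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
    L = codes.shape[1]
    if L < k:
        return np.empty((codes.shape[0], 0), dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    nwin = L - k + 1
    out = np.zeros((codes.shape[0], nwin), dtype=np.int64)
    for j in range(k):
        out += codes[:, j : j + nwin] * powers[j]
    return out


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return COMPLEMENT[np.asarray(codes)][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def revcomp_index_permutation(k: int) -> np.ndarray:
    """perm[i] = index of the reverse complement of k-mer i."""
    codes = all_kmer_codes(k).astype(np.int64)
    rc = revcomp_codes(codes)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return rc @ powers


def rc_class_representatives(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-complement equivalence classes {s, revcomp(s)}.

    Returns ``(reps, class_of)``: ``reps`` lists one representative index
    per class (the smaller of the pair), ``class_of[i]`` maps each k-mer
    to its class number (position within ``reps``).
    """
    perm = revcomp_index_permutation(k)
    idx = np.arange(4**k)
    reps_mask = idx <= perm
    reps = idx[reps_mask]
    class_of = np.empty(4**k, dtype=np.int64)
    class_of[reps] = np.arange(reps.size)
    class_of[perm[reps]] = np.arange(reps.size)
    return reps, class_of
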