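"""Exhaustive, ordered, chunked enumeration of the complete 4^k k-mer space.

K-mers are indexed lexicographically with A < C < G < T: index i is the
base-4 expansion of i, most-significant digit first, under A=0, C=1, G=2,
T=3.  Representations (ASCII or gen32-packed bytes) are synthesized
arithmetically from the digit arrays, so no intermediate Python strings are
materialized even at k = 16 (4^16 ≈ 4.3e9 inputs, streamed in chunks).
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np

from .packing import packed_size

__all__ = [
    "ALPHABET",
    "total_kmers",
    "index_to_kmer",
    "kmer_to_index",
    "indices_to_ascii",
    "indices_to_packed",
    "enumerate_ascii",
    "enumerate_packed",
    "DEFAULT_CHUNK",
]

ALPHABET = "ACGT"
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
#: gen32 codes in digit order: A, C, G, T.
_CODES = np.array([0x0, 0x2, 0x6, 0x4], dtype=np.uint8)
_DIGIT_OF = {c: d for d, c in enumerate(ALPHABET)}

#: Default chunk: 2^22 items keeps every per-chunk array well under 64 MB.
DEFAULT_CHUNK = 1 << 22


def total_kmers(k: int) -> int:
    """4^k, the size of the complete k-mer space."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4**k


def index_to_kmer(idx: int, k: int) -> str:
    """k-mer at lexicographic index *idx* (A<C<G<T)."""
    if not 0 <= idx < total_kmers(k):
        raise ValueError(f"index {idx} out of range for k={k}")
    return "".join(ALPHABET[(idx >> (2 * (k - 1 - j))) & 3] for j in range(k))


def kmer_to_index(sequence: str) -> int:
    """Inverse of :func:`index_to_kmer` (case-insensitive)."""
    idx = 0
    for ch in sequence.upper():
        try:
            idx = (idx << 2) | _DIGIT_OF[ch]
        except KeyError:
            raise ValueError(f"invalid nucleotide {ch!r}") from None
    return idx


def _digits(indices: np.ndarray, k: int) -> np.ndarray:
    """(n, k) int8 base-4 digit array, most-significant digit first."""
    idx = np.asarray(indices, dtype=np.uint64)
    shifts = (2 * (k - 1 - np.arange(k, dtype=np.uint64))).astype(np.uint64)
    return ((idx[:, None] >> shifts[None, :]) & np.uint64(3)).astype(np.uint8)


def indices_to_ascii(indices: np.ndarray, k: int) -> np.ndarray:
    """(n, k) uint8 uppercase-ASCII representation of the given indices."""
    return _ASCII[_digits(indices, k)]


def indices_to_packed(indices: np.ndarray, k: int) -> np.ndarray:
    """(n, ceil(k/2)) uint8 gen32-packed representation of the given indices.

    Bit-identical to packing the ASCII form, but synthesized directly from
    the digit arrays via the nibble code map.
    """
    codes = _CODES[_digits(indices, k)]
    n = codes.shape[0]
    out = np.zeros((n, packed_size(k)), dtype=np.uint8)
    out[:, : k // 2] = (codes[:, 0 : k - 1 : 2] << 4) | codes[:, 1:k:2]
    if k % 2:
        out[:, -1] = codes[:, -1]
    return out


def _chunked_indices(k: int, chunk: int) -> Iterator[np.ndarray]:
    total = total_kmers(k)
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        yield np.arange(start, stop, dtype=np.uint64)


def enumerate_ascii(k: int, chunk: int = DEFAULT_CHUNK) -> Iterator[np.ndarray]:
    """Yield the complete 4^k space as (<=chunk, k) uint8 ASCII blocks, in index order."""
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    for idx in _chunked_indices(k, chunk):
        yield indices_to_ascii(idx, k)


def enumerate_packed(k: int, chunk: int = DEFAULT_CHUNK) -> Iterator[np.ndarray]:
    """Yield the complete 4^k space as gen32-packed byte blocks, in index order."""
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    for idx in _chunked_indices(k, chunk):
        yield indices_to_packed(idx, k)
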