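"""gen32 nucleotide packing.

A DNA k-mer over {A,C,G,T} (either case) is converted to ``ceil(k/2)`` bytes
by masking each ASCII byte with 0x0E — which isolates bits 1-3, the bits that
distinguish the four nucleotides and are identical across upper and lower
case — and packing two 4-bit codes per byte.  The resulting codes are

    A/a -> 0x0,  C/c -> 0x2,  G/g -> 0x6,  T/t -> 0x4

An even-indexed base occupies the high nibble of its byte, its successor the
low nibble; for odd k the final lone code sits in the low nibble of the last
byte (high nibble zero).  On the four-letter alphabet the map is injective
for every fixed k, which is what makes a downstream collision-free 32-bit
hash possible at all for k <= 16.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NIBBLE_MASK",
    "NIBBLE_CODES",
    "encode_nibble",
    "validate_kmer",
    "packed_size",
    "gen32_pack",
    "pack_batch",
    "kmers_to_ascii",
    "ascii_to_kmers",
]

NIBBLE_MASK = 0x0E

#: 4-bit code of each nucleotide (== ord(base) & 0x0E, case-insensitive).
NIBBLE_CODES = {"A": 0x0, "C": 0x2, "G": 0x6, "T": 0x4}

# uint8 lookup: True for the eight permitted ASCII letters.
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTacgt":
    _VALID[ord(_b)] = True


def validate_kmer(sequence: str) -> None:
    """Raise ``ValueError`` unless *sequence* is a nonempty ACGT/acgt string.

    The error message names the first offending position (0-based).
    """
    if len(sequence) == 0:
        raise ValueError("empty k-mer")
    for i, ch in enumerate(sequence):
        if not _VALID[ord(ch) & 0xFF] or ord(ch) > 0xFF:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {i}: expected one of ACGT/acgt"
            )


def encode_nibble(base: str, strict: bool = True) -> int:
    """4-bit gen32 code of a single nucleotide: ``ord(base) & 0x0E``.

    In strict mode a non-ACGT character raises ``ValueError``; in permissive
    mode the masked value is returned unchecked (useful only for benchmarking
    parity with raw hashes — the mask is injective only on ACGT).
    """
    if len(base) != 1:
        raise ValueError("encode_nibble expects a single character")
    if strict:
        validate_kmer(base)
    return ord(base) & NIBBLE_MASK


def packed_size(k: int) -> int:
    """Byte count of the packed representation: ``(k // 2) + (k % 2)``."""
    return (k // 2) + (k % 2)


def gen32_pack(sequence: str, strict: bool = True) -> bytes:
    """Pack a k-mer into its ``ceil(k/2)``-byte gen32 representation.

    >>> gen32_pack("ACGT").hex()
    '0264'
    """
    if strict:
        validate_kmer(sequence)
    elif len(sequence) == 0:
        raise ValueError("empty k-mer")
    result = bytearray(packed_size(len(sequence)))
    for i, ch in enumerate(sequence):
        code = ord(ch) & NIBBLE_MASK
        result[i // 2] = ((result[i // 2] << 4) | code) & 0xFF
    return bytes(result)


def pack_batch(ascii_kmers: np.ndarray, strict: bool = True) -> np.ndarray:
    """Vectorized gen32 packing of same-length k-mers.

    Parameters
    ----------
    ascii_kmers
        ``(n, k)`` uint8 array of ASCII nucleotide codes.
    strict
        Validate the alphabet (raises ``ValueError`` naming the first bad
        row/column) before masking.

    Returns
    -------
    ``(n, ceil(k/2))`` uint8 array, elementwise equal to ``gen32_pack``.
    """
    a = np.asarray(ascii_kmers, dtype=np.uint8)
    if a.ndim != 2 or a.shape[1] == 0:
        raise ValueError("expected a nonempty (n, k) array of ASCII codes")
    if strict:
        bad = ~_VALID[a]
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid nucleotide byte 0x{a[r, c]:02X} in k-mer {r} at position {c}"
            )
    codes = a & NIBBLE_MASK
    n, k = codes.shape
    out = np.zeros((n, packed_size(k)), dtype=np.uint8)
    out[:, : k // 2] = (codes[:, 0 : k - 1 : 2] << 4) | codes[:, 1:k:2]
    if k % 2:
        out[:, -1] = codes[:, -1]  # lone trailing code: low nibble, high nibble 0
    return out


def kmers_to_ascii(kmers: list[str] | tuple[str, ...]) -> np.ndarray:
    """Stack same-length k-mer strings into an ``(n, k)`` uint8 ASCII array."""
    if len(kmers) == 0:
        raise ValueError("empty k-mer list")
    k = len(kmers[0])
    if any(len(s) != k for s in kmers):
        raise ValueError("k-mers have mixed lengths")
    buf = "".join(kmers).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(kmers), k)


def ascii_to_kmers(ascii_kmers: np.ndarray) -> list[str]:
    """Inverse of :func:`kmers_to_ascii`."""
    a = np.ascontiguousarray(ascii_kmers, dtype=np.uint8)
    n, k = a.shape
    s = a.tobytes().decode("ascii")
    return [s[i * k : (i + 1) * k] for i in range(n)]
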