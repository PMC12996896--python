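"""MurmurHash3 (x86, 32-bit) and xxHash32, scalar and vectorized.

Both algorithms are implemented from their public specifications and checked
in the test suite against canonical published check values (and, for
MurmurHash3, against scikit-learn's murmurhash3_32).  The vectorized forms
hash every row of an ``(n, L)`` uint8 array in one pass; because L <= 16 for
in-scope k-mers the per-row block loops unroll to at most four iterations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["murmur3_32", "murmur3_32_batch", "xxhash32", "xxhash32_batch"]

_M = 0xFFFFFFFF


def _rotl(x: int, r: int) -> int:
    return ((x << r) | (x >> (32 - r))) & _M


# ---------------------------------------------------------------------------
# MurmurHash3 x86_32

_MM_C1 = 0xCC9E2D51
_MM_C2 = 0x1B873593


def murmur3_32(data: bytes, seed: int = 0) -> int:
    """MurmurHash3 x86 32-bit of a byte string."""
    h = seed & _M
    n = len(data)
    nblocks = n // 4
    for i in range(nblocks):
        k = int.from_bytes(data[4 * i : 4 * i + 4], "little")
        k = (k * _MM_C1) & _M
        k = _rotl(k, 15)
        k = (k * _MM_C2) & _M
        h ^= k
        h = _rotl(h, 13)
        h = (h * 5 + 0xE6546B64) & _M
    k = 0
    tail = data[4 * nblocks :]
    if len(tail) >= 3:
        k ^= tail[2] << 16
    if len(tail) >= 2:
        k ^= tail[1] << 8
    if len(tail) >= 1:
        k ^= tail[0]
        k = (k * _MM_C1) & _M
        k = _rotl(k, 15)
        k = (k * _MM_C2) & _M
        h ^= k
    h ^= n
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & _M
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & _M
    h ^= h >> 16
    return h


def _rotl_v(x: np.ndarray, r: int) -> np.ndarray:
    return (x << np.uint32(r)) | (x >> np.uint32(32 - r))


def _le32(rows: np.ndarray, start: int) -> np.ndarray:
    """Little-endian uint32 lane from byte columns start..start+3."""
    r = rows
    return (
        r[:, start].astype(np.uint32)
        | (r[:, start + 1].astype(np.uint32) << np.uint32(8))
        | (r[:, start + 2].astype(np.uint32) << np.uint32(16))
        | (r[:, start + 3].astype(np.uint32) << np.uint32(24))
    )


def murmur3_32_batch(rows: np.ndarray, seed: int = 0) -> np.ndarray:
    """MurmurHash3 x86_32 of each row of an ``(n, L)`` uint8 array."""
    a = np.asarray(rows, dtype=np.uint8)
    if a.ndim != 2:
        raise ValueError("expected an (n, L) uint8 array")
    n, L = a.shape
    c1 = np.uint32(_MM_C1)
    c2 = np.uint32(_MM_C2)
    h = np.full(n, seed & _M, dtype=np.uint32)
    for i in range(L // 4):
        k = _le32(a, 4 * i)
        k *= c1
        k = _rotl_v(k, 15)
        k *= c2
        h ^= k
        h = _rotl_v(h, 13)
        h = h * np.uint32(5) + np.uint32(0xE6546B64)
    tail = L % 4
    if tail:
        k = np.zeros(n, dtype=np.uint32)
        base = L - tail
        if tail >= 3:
            k ^= a[:, base + 2].astype(np.uint32) << np.uint32(16)
        if tail >= 2:
            k ^= a[:, base + 1].astype(np.uint32) << np.uint32(8)
        k ^= a[:, base].astype(np.uint32)
        k *= c1
        k = _rotl_v(k, 15)
        k *= c2
        h ^= k
    h ^= np.uint32(L)
    h ^= h >> np.uint32(16)
    h *= np.uint32(0x85EBCA6B)
    h ^= h >> np.uint32(13)
    h *= np.uint32(0xC2B2AE35)
    h ^= h >> np.uint32(16)
    return h


# ---------------------------------------------------------------------------
# xxHash32

_XX_P1 = 0x9E3779B1
_XX_P2 = 0x85EBCA77
_XX_P3 = 0xC2B2AE3D
_XX_P4 = 0x27D4EB2F
_XX_P5 = 0x165667B1


def xxhash32(data: bytes, seed: int = 0) -> int:
    """xxHash32 of a byte string."""
    n = len(data)
    seed &= _M
    i = 0
    if n >= 16:
        acc = [
            (seed + _XX_P1 + _XX_P2) & _M,
            (seed + _XX_P2) & _M,
            seed,
            (seed - _XX_P1) & _M,
        ]
        while i + 16 <= n:
            for lane in range(4):
                v = int.from_bytes(data[i + 4 * lane : i + 4 * lane + 4], "little")
                acc[lane] = (_rotl((acc[lane] + v * _XX_P2) & _M, 13) * _XX_P1) & _M
            i += 16
        h = (_rotl(acc[0], 1) + _rotl(acc[1], 7) + _rotl(acc[2], 12) + _rotl(acc[3], 18)) & _M
    else:
        h = (seed + _XX_P5) & _M
    h = (h + n) & _M
    while i + 4 <= n:
        v = int.from_bytes(data[i : i + 4], "little")
        h = (_rotl((h + v * _XX_P3) & _M, 17) * _XX_P4) & _M
        i += 4
    while i < n:
        h = (_rotl((h + data[i] * _XX_P5) & _M, 11) * _XX_P1) & _M
        i += 1
    h ^= h >> 15
    h = (h * _XX_P2) & _M
    h ^= h >> 13
    h = (h * _XX_P3) & _M
    h ^= h >> 16
    return h


def xxhash32_batch(rows: np.ndarray, seed: int = 0) -> np.ndarray:
    """xxHash32 of each row of an ``(n, L)`` uint8 array."""
    a = np.asarray(rows, dtype=np.uint8)
    if a.ndim != 2:
        raise ValueError("expected an (n, L) uint8 array")
    n, L = a.shape
    p1 = np.uint32(_XX_P1)
    p2 = np.uint32(_XX_P2)
    p3 = np.uint32(_XX_P3)
    p4 = np.uint32(_XX_P4)
    p5 = np.uint32(_XX_P5)
    s = np.uint32(seed & _M)
    i = 0
    if L >= 16:
        acc = [s + p1 + p2, s + p2, s + np.uint32(0), s - p1]
        acc = [np.full(n, v, dtype=np.uint32) for v in acc]
        while i + 16 <= L:
            for lane in range(4):
                v = _le32(a, i + 4 * lane)
                acc[lane] = _rotl_v(acc[lane] + v * p2, 13) * p1
            i += 16
        h = _rotl_v(acc[0], 1) + _rotl_v(acc[1], 7) + _rotl_v(acc[2], 12) + _rotl_v(acc[3], 18)
    else:
        h = np.full(n, s + p5, dtype=np.uint32)
    h = h + np.uint32(L)
    while i + 4 <= L:
        h = _rotl_v(h + _le32(a, i) * p3, 17) * p4
        i += 4
    while i < L:
        h = _rotl_v(h + a[:, i].astype(np.uint32) * p5, 11) * p1
        i += 1
    h ^= h >> np.uint32(15)
    h *= p2
    h ^= h >> np.uint32(13)
    h *= p3
    h ^= h >> np.uint32(16)
    return h
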