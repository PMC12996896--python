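"""Reflected (LSB-first) table-driven CRC32 with an arbitrary reversed-form polynomial.

All polynomial constants here are in reversed (LSB-first) form — e.g.
0xEDB88320 is the ubiquitous CRC-32, 0x82F63B78 is CRC-32C.  The register is
initialized to 0xFFFFFFFF and the final value is XORed with 0xFFFFFFFF,
i.e. the convention of Go's hash/crc32 and Python's zlib.crc32.

The module carries the 20-candidate polynomial panel screened for
collision-free k-mer hashing and the eight survivors that, combined with
gen32 packing, are injective on every complete 4^k space up to k = 16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CrcParams",
    "CANDIDATE_POLYS",
    "COLLISION_FREE_POLYS",
    "build_table",
    "crc32_bytes",
    "crc32_bitwise",
    "crc32_batch",
    "gencrc32",
]

#: The 20 reversed-form 32-bit polynomial candidates screened for k-mer hashing.
CANDIDATE_POLYS: tuple[int, ...] = (
    0xEB31D82E, 0xEDB88320, 0x82F63B78, 0xAD0424F3, 0x945D045D,
    0x9D9947FD, 0xA3000000, 0x87496166, 0x8E2371EF, 0x8C746ED4,
    0x8EFD4BCD, 0x80000057, 0x8741C726, 0x82608EDB, 0x8EE5368F,
    0xE47B4C57, 0xD2C0EF07, 0x80FCB077, 0x93B39B1B, 0xB338ADD6,
)

#: The eight polynomials whose gen32+CRC32 map is collision-free for all k <= 16.
COLLISION_FREE_POLYS: tuple[int, ...] = (
    0x8741C726, 0x87496166, 0x8E2371EF, 0x8EE5368F,
    0x8EFD4BCD, 0x945D045D, 0x9D9947FD, 0xEB31D82E,
)

_MASK32 = 0xFFFFFFFF


@dataclass(frozen=True)
class CrcParams:
    """One reflected CRC32 variant.

    Attributes
    ----------
    poly_reversed
        32-bit divisor in reversed (LSB-first) bit order.
    init, xor_out
        Register preset and final XOR; both default to 0xFFFFFFFF.
    """

    poly_reversed: int
    init: int = 0xFFFFFFFF
    xor_out: int = 0xFFFFFFFF

    def __post_init__(self) -> None:
        for name in ("poly_reversed", "init", "xor_out"):
            v = getattr(self, name)
            if not (0 <= v <= _MASK32):
                raise ValueError(f"{name} must be a 32-bit unsigned integer, got {v:#x}")
        if self.poly_reversed == 0:
            raise ValueError("polynomial must be nonzero")


_table_cache: dict[int, np.ndarray] = {}


def build_table(params: CrcParams) -> np.ndarray:
    """256-entry lookup table: entry i is 8 reflected shift-reduce steps on byte i."""
    poly = params.poly_reversed
    tbl = _table_cache.get(poly)
    if tbl is not None:
        return tbl
    entries = np.arange(256, dtype=np.uint32)
    for _ in range(8):
        low = entries & 1
        entries = (entries >> 1) ^ (np.uint32(poly) * low)
    _table_cache[poly] = entries
    entries.setflags(write=False)
    return entries


def crc32_bytes(data: bytes | bytearray | memoryview, params: CrcParams) -> int:
    """Table-driven reflected CRC32 of a byte string (scalar)."""
    tbl = build_table(params)
    reg = params.init
    for b in bytes(data):
        reg = int(tbl[(reg ^ b) & 0xFF]) ^ (reg >> 8)
    return reg ^ params.xor_out


def crc32_bitwise(data: bytes | bytearray | memoryview, params: CrcParams) -> int:
    """Bit-at-a-time reflected CRC32 — the table-free reference form.

    Kept deliberately independent of :func:`crc32_bytes`; used to validate
    the table construction.
    """
    reg = params.init
    for b in bytes(data):
        reg ^= b
        for _ in range(8):
            reg = (reg >> 1) ^ (params.poly_reversed if reg & 1 else 0)
    return reg ^ params.xor_out


def crc32_batch(rows: np.ndarray, params: CrcParams) -> np.ndarray:
    """Reflected CRC32 of each row of an ``(n, L)`` uint8 array.

    Processes the n messages column-by-column with one table lookup per
    byte position, so the cost is O(n·L) with numpy-level constants.
    Elementwise equal to :func:`crc32_bytes`.
    """
    a = np.asarray(rows, dtype=np.uint8)
    if a.ndim != 2:
        raise ValueError("expected an (n, L) uint8 array")
    tbl = build_table(params)
    reg = np.full(a.shape[0], params.init, dtype=np.uint32)
    for j in range(a.shape[1]):
        reg = tbl[(reg ^ a[:, j]) & np.uint32(0xFF)] ^ (reg >> np.uint32(8))
    return reg ^ np.uint32(params.xor_out)


def gencrc32(sequence: str, params: CrcParams, strict: bool = True) -> int:
    """gen32-pack a k-mer, then CRC32 the packed bytes: the full hashing scheme."""
    from .packing import gen32_pack

    return crc32_bytes(gen32_pack(sequence, strict=strict), params)
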