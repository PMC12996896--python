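"""Uniform adapter layer over every benchmarked hash configuration.

A :class:`HashConfig` is one cell of the evaluation grid
``{none, gen32} x {crc32(poly), murmur3_32, xxhash32}`` — a single callable
identity with a stable label such as ``"gen32+crc32:0x8741C726"`` or
``"none+murmur3_32:0"`` (the trailing field is the polynomial for CRC32 and
the seed for the third-party families).  Raw mode hashes the uppercase ASCII
bytes of the k-mer; gen32 mode hashes the packed bytes, so both modes see
the same logical k-mer set.

Additional 32-bit hash families (e.g. external ntHash or PHast bindings)
can be plugged in with :func:`register_family`; none are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .crc import CANDIDATE_POLYS, CrcParams, crc32_batch, crc32_bytes
from .hashes32 import murmur3_32, murmur3_32_batch, xxhash32, xxhash32_batch
from .packing import gen32_pack, kmers_to_ascii, pack_batch

__all__ = [
    "HashConfig",
    "parse_label",
    "hash_kmer",
    "hash_batch",
    "benchmark_grid",
    "register_family",
    "available_families",
]

PREPROCESSINGS = ("none", "gen32")

# family name -> (scalar fn(bytes, seed) -> int, batch fn(rows, seed) -> uint32[n])
_FAMILIES: dict[str, tuple[Callable[..., int], Callable[..., np.ndarray]]] = {
    "murmur3_32": (murmur3_32, murmur3_32_batch),
    "xxhash32": (xxhash32, xxhash32_batch),
}


def register_family(
    name: str,
    scalar_fn: Callable[[bytes, int], int],
    batch_fn: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> None:
    """Plug in an external seeded 32-bit hash family.

    ``batch_fn`` defaults to a row loop over ``scalar_fn``.
    """
    if name in ("crc32",) or name in _FAMILIES:
        raise ValueError(f"family {name!r} already registered")
    if batch_fn is None:
        def batch_fn(rows: np.ndarray, seed: int = 0) -> np.ndarray:  # noqa: ANN001
            a = np.ascontiguousarray(rows, dtype=np.uint8)
            return np.array([scalar_fn(r.tobytes(), seed) for r in a], dtype=np.uint32)
    _FAMILIES[name] = (scalar_fn, batch_fn)


def available_families() -> tuple[str, ...]:
    return ("crc32", *_FAMILIES)


@dataclass(frozen=True)
class HashConfig:
    """One benchmarked hashing protocol: preprocessing x family x parameters."""

    preprocessing: str
    family: str
    params: CrcParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preprocessing not in PREPROCESSINGS:
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.family == "crc32":
            if self.params is None:
                raise ValueError("crc32 configs require CrcParams")
        elif self.family in _FAMILIES:
            if self.params is not None:
                raise ValueError(f"{self.family} configs take a seed, not CrcParams")
            if not 0 <= self.seed <= 0xFFFFFFFF:
                raise ValueError("seed must be a 32-bit unsigned integer")
        else:
            raise ValueError(
                f"unknown family {self.family!r}; available: {available_families()}"
            )

    @property
    def label(self) -> str:
        if self.family == "crc32":
            return f"{self.preprocessing}+crc32:0x{self.params.poly_reversed:08X}"
        return f"{self.preprocessing}+{self.family}:{self.seed}"

    @classmethod
    def crc(cls, poly_reversed: int, preprocessing: str = "gen32") -> "HashConfig":
        """Shorthand for a CRC32 config with the default register convention."""
        return cls(preprocessing, "crc32", params=CrcParams(poly_reversed))


def parse_label(label: str) -> HashConfig:
    """Inverse of :attr:`HashConfig.label`."""
    try:
        prep, rest = label.split("+", 1)
        family, param = rest.split(":", 1)
    except ValueError:
        raise ValueError(
            f"malformed config label {label!r}; expected e.g. 'gen32+crc32:0x8741C726'"
        ) from None
    if family == "crc32":
        return HashConfig(prep, "crc32", params=CrcParams(int(param, 16)))
    return HashConfig(prep, family, seed=int(param, 0))


def _raw_ascii(kmer: str) -> bytes:
    return kmer.upper().encode("ascii")


def hash_kmer(config: HashConfig, kmer: str, strict: bool = True) -> int:
    """32-bit hash of a single k-mer under *config*."""
    if config.preprocessing == "gen32":
        data = gen32_pack(kmer, strict=strict)
    else:
        if strict:
            from .packing import validate_kmer

            validate_kmer(kmer)
        data = _raw_ascii(kmer)
    if config.family == "crc32":
        return crc32_bytes(data, config.params)
    return _FAMILIES[config.family][0](data, config.seed)


def _upper_ascii_batch(a: np.ndarray) -> np.ndarray:
    # a-z -> A-Z; other bytes untouched
    lower = (a >= 0x61) & (a <= 0x7A)
    return np.where(lower, a - np.uint8(0x20), a)


def hash_batch(config: HashConfig, kmers: np.ndarray | list[str], strict: bool = True) -> np.ndarray:
    """Vectorized :func:`hash_kmer` over same-length k-mers (order preserved).

    ``kmers`` may be a list of equal-length strings or an ``(n, k)`` uint8
    ASCII array.  Mixed lengths raise ``ValueError``.
    """
    if isinstance(kmers, (list, tuple)):
        a = kmers_to_ascii(kmers)
    else:
        a = np.asarray(kmers, dtype=np.uint8)
        if a.ndim != 2:
            raise ValueError("expected an (n, k) ASCII array or a list of k-mer strings")
    return hash_packed_or_raw(config, a, strict=strict)


def hash_packed_or_raw(config: HashConfig, ascii_kmers: np.ndarray, strict: bool = True) -> np.ndarray:
    """Hash an (n, k) ASCII array under *config* (internal batch core)."""
    if config.preprocessing == "gen32":
        data = pack_batch(ascii_kmers, strict=strict)
    else:
        if strict:
            pack_batch(ascii_kmers, strict=True)  # alphabet check only
        data = _upper_ascii_batch(np.asarray(ascii_kmers, dtype=np.uint8))
    return hash_representation(config, data)


def hash_representation(config: HashConfig, rows: np.ndarray) -> np.ndarray:
    """Hash already-encoded representation rows (packed bytes or raw ASCII)."""
    if config.family == "crc32":
        return crc32_batch(rows, config.params)
    with np.errstate(over="ignore"):
        return _FAMILIES[config.family][1](rows, config.seed)


def benchmark_grid(polys: tuple[int, ...] = CANDIDATE_POLYS, seed: int = 0) -> list[HashConfig]:
    """The full evaluation grid: every polynomial and third-party family, raw and gen32."""
    grid: list[HashConfig] = []
    for prep in PREPROCESSINGS:
        for poly in polys:
            grid.append(HashConfig(prep, "crc32", params=CrcParams(poly)))
        grid.append(HashConfig(prep, "murmur3_32", seed=seed))
        grid.append(HashConfig(prep, "xxhash32", seed=seed))
    return grid
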