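"""Exact collision audits over complete 4^k k-mer spaces.

For a hash configuration and k, the audit hashes every one of the 4^k
k-mers and counts distinct 32-bit values; ``collisions = 4^k - distinct``
and the map is injective at k iff collisions == 0.  Two backends return
identical counts:

* ``array`` — materialize all hash values, sort-unique.  Used up to k = 13
  (<= 67M x 4 bytes).
* ``bitset`` — a 512 MB occupancy bitset over the full 2^32 output space,
  streamed chunk by chunk and counting first-set events.  Bounds memory for
  k = 14..16, where the array backend would not fit comfortably.

``first_collision_k`` scans k ascending for the collision onset (the lower
boundary of a configuration's "k range with collisions"), and
``screen_polynomials`` retains the CRC32 polynomials whose gen32 variant is
injective for every k in 4..k_max.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .crc import CrcParams
from .kmerspace import (
    DEFAULT_CHUNK,
    indices_to_ascii,
    indices_to_packed,
    total_kmers,
)
from .registry import HashConfig, hash_representation

__all__ = [
    "CollisionReport",
    "count_collisions",
    "first_collision_k",
    "screen_polynomials",
    "replicate_audit",
]

#: Largest k audited without force=True (4^17 > 2^32 cannot be injective).
K_LIMIT = 16
_ARRAY_BACKEND_MAX_K = 13


@dataclass(frozen=True)
class CollisionReport:
    """Result of one exhaustive audit (one configuration at one k)."""

    config_label: str
    k: int
    total: int
    distinct: int
    collisions: int
    replicates: int = 1
    consistent: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _representation_chunks(config: HashConfig, k: int, chunk: int, indices=None):
    """Yield representation blocks (packed or uppercase ASCII) for the space."""
    total = total_kmers(k)
    make = indices_to_packed if config.preprocessing == "gen32" else indices_to_ascii
    if indices is None:
        for start in range(0, total, chunk):
            yield make(np.arange(start, min(start + chunk, total), dtype=np.uint64), k)
    else:
        for start in range(0, len(indices), chunk):
            yield make(indices[start : start + chunk].astype(np.uint64), k)


def _guard_k(k: int, force: bool) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > K_LIMIT and not force:
        raise ValueError(
            f"k={k} exceeds the 32-bit injectivity limit (4^{k} > 2^32); "
            "pass force=True to audit anyway"
        )
    if not 4 <= k <= K_LIMIT:
        warnings.warn(f"k={k} is outside the usual audit range 4..16", stacklevel=3)


def _distinct_array(config: HashConfig, k: int, chunk: int, indices=None) -> int:
    total = total_kmers(k) if indices is None else len(indices)
    hashes = np.empty(total, dtype=np.uint32)
    pos = 0
    for rows in _representation_chunks(config, k, chunk, indices):
        hashes[pos : pos + len(rows)] = hash_representation(config, rows)
        pos += len(rows)
    return int(np.unique(hashes).size)


def _distinct_bitset(config: HashConfig, k: int, chunk: int) -> int:
    seen = np.zeros(1 << 29, dtype=np.uint8)  # 2^32 bits
    distinct = 0
    for rows in _representation_chunks(config, k, chunk):
        h = np.unique(hash_representation(config, rows))
        byte_idx = h >> np.uint32(3)
        bits = (np.uint8(1) << (h & np.uint32(7)).astype(np.uint8))
        distinct += int(np.count_nonzero((seen[byte_idx] & bits) == 0))
        np.bitwise_or.at(seen, byte_idx, bits)
    return distinct


def count_collisions(
    config: HashConfig,
    k: int,
    backend: str = "auto",
    chunk: int = DEFAULT_CHUNK,
    force: bool = False,
) -> CollisionReport:
    """Exact distinct-hash count of *config* over the complete 4^k space.

    Deterministic for a fixed configuration; results are independent of
    ``chunk`` and ``backend``.
    """
    _guard_k(k, force)
    if backend == "auto":
        backend = "array" if k <= _ARRAY_BACKEND_MAX_K else "bitset"
    if backend == "array":
        distinct = _distinct_array(config, k, chunk)
    elif backend == "bitset":
        distinct = _distinct_bitset(config, k, chunk)
    else:
        raise ValueError(f"unknown backend {backend!r}; use 'array', 'bitset' or 'auto'")
    total = total_kmers(k)
    return CollisionReport(config.label, k, total, distinct, total - distinct)


def first_collision_k(
    config: HashConfig,
    k_min: int = 4,
    k_max: int = K_LIMIT,
    backend: str = "auto",
    chunk: int = DEFAULT_CHUNK,
    force: bool = False,
) -> int | None:
    """Smallest k in [k_min, k_max] with at least one collision, or None.

    A returned onset implies every smaller k in the range is collision-free.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    for k in range(k_min, k_max + 1):
        if count_collisions(config, k, backend=backend, chunk=chunk, force=force).collisions:
            return k
    return None


def screen_polynomials(
    polys: list[CrcParams] | list[int],
    k_max: int,
    k_min: int = 4,
    chunk: int = DEFAULT_CHUNK,
) -> list[CrcParams]:
    """CRC32 polynomials whose gen32 variant is collision-free for all k in [k_min, k_max].

    Scans k ascending and drops a candidate at its first colliding k, so the
    cheap small-k spaces eliminate nothing and the expensive large-k spaces
    are hashed only for surviving candidates.  Order is preserved.
    """
    if not polys:
        raise ValueError("empty candidate list")
    params = [p if isinstance(p, CrcParams) else CrcParams(p) for p in polys]
    survivors = list(params)
    for k in range(k_min, k_max + 1):
        _guard_k(k, force=False)
        total = total_kmers(k)
        # Materialize the packed space once per k when it fits (<= ~470 MB),
        # then hash it under each surviving polynomial.
        from .packing import packed_size

        if total * packed_size(k) <= (1 << 29):
            packed = indices_to_packed(np.arange(total, dtype=np.uint64), k)
            still = []
            for p in survivors:
                cfg = HashConfig("gen32", "crc32", params=p)
                if int(np.unique(hash_representation(cfg, packed)).size) == total:
                    still.append(p)
            survivors = still
        else:
            survivors = [
                p
                for p in survivors
                if count_collisions(
                    HashConfig("gen32", "crc32", params=p), k, chunk=chunk
                ).collisions
                == 0
            ]
        if not survivors:
            break
    return survivors


def replicate_audit(
    config: HashConfig,
    k: int,
    reps: int = 10,
    order_seed: int = 0,
    chunk: int = DEFAULT_CHUNK,
) -> CollisionReport:
    """*reps* independent audits of the complete space in shuffled processing order.

    The hash map is deterministic, so every replicate must report the same
    collision count; ``consistent`` is False (and the first replicate's count
    is reported) if any disagree.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _guard_k(k, force=False)
    if k > _ARRAY_BACKEND_MAX_K:
        raise ValueError("replicate_audit supports k <= 13 (shuffled index array)")
    total = total_kmers(k)
    rng = np.random.default_rng(order_seed)
    counts = []
    for _ in range(reps):
        order = rng.permutation(total)
        counts.append(total - _distinct_array(config, k, chunk, indices=order))
    consistent = len(set(counts)) == 1
    return CollisionReport(
        config.label, k, total, total - counts[0], counts[0], reps, consistent
    )
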