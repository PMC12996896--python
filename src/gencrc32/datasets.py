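"""Workload generators: the Random / Similar / Window k-mer regimes and a
synthetic genome standing in for a real bacterial reference.

Each regime yields n k-mers (1,000,000 by default in the evaluation
protocol) and is fully reproducible from its seed:

* Random — every base i.i.d. uniform over {A,C,G,T}.
* Similar — a near-neighbor chain: the first k-mer is uniform random and
  each subsequent one is a single-base edit of its predecessor (duplicates
  permitted; this is a workload, not a key set).
* Window — overlapping step-1 sliding windows over a FASTA sequence,
  skipping windows that contain non-ACGT characters.

The synthetic genome writer emits a single-record FASTA with i.i.d. bases
at a chosen GC fraction (default 4.6 Mb at GC 0.508, echoing the E. coli
K-12 chromosome) so the Window regime never requires a download; any real
FASTA can be supplied instead.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

from .packing import ascii_to_kmers

__all__ = [
    "random_kmers",
    "similar_chain",
    "window_kmers",
    "synthetic_genome",
    "read_fasta_sequences",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _BASE_INDEX[ord(_c)] = _i
    _BASE_INDEX[ord(_c.lower())] = _i

# E. coli K-12 MG1655-like defaults for the stand-in genome.
DEFAULT_GENOME_LENGTH = 4_600_000
DEFAULT_GC = 0.508


def _as_output(ascii_array: np.ndarray, as_array: bool) -> np.ndarray | list[str]:
    return ascii_array if as_array else ascii_to_kmers(ascii_array)


def random_kmers(
    n: int, k: int, seed: int | np.random.Generator = 0, as_array: bool = False
) -> np.ndarray | list[str]:
    """n uniform random k-mers (each base i.i.d. over ACGT)."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = _ALPHABET[rng.integers(4, size=(n, k))]
    return _as_output(a, as_array)


def similar_chain(
    n: int, k: int, seed: int | np.random.Generator = 0, as_array: bool = False
) -> np.ndarray | list[str]:
    """Near-neighbor chain: element i+1 is a single-base edit of element i.

    Consecutive elements are at Hamming distance exactly 1; revisits and
    duplicates further apart are permitted.  Vectorized by noting that each
    edit adds a nonzero offset (mod 4) to one position's base index, so the
    base at position j after i steps is the initial base plus the cumulative
    sum of the offsets of the edits that hit j.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = rng.integers(4, size=k, dtype=np.int64)
    if n == 1:
        return _as_output(_ALPHABET[init][None, :], as_array)
    pos = rng.integers(k, size=n - 1)
    offset = rng.integers(1, 4, size=n - 1, dtype=np.int64)
    contrib = np.zeros((n, k), dtype=np.int64)
    contrib[np.arange(1, n), pos] = offset
    digits = (init[None, :] + np.cumsum(contrib, axis=0)) % 4
    return _as_output(_ALPHABET[digits], as_array)


def read_fasta_sequences(path: str | Path) -> list[str]:
    """All record sequences of a FASTA file, in file order, as plain strings."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def window_kmers(
    fasta: str | Path, k: int, n: int, as_array: bool = False
) -> np.ndarray | list[str]:
    """First n admissible step-1 sliding windows over a FASTA file.

    Windows run within records (never across record boundaries), start at
    position 0, and any window containing a non-ACGT character is skipped.
    Raises ``ValueError`` naming the shortfall if fewer than n admissible
    windows exist.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    blocks: list[np.ndarray] = []
    found = 0
    for seq in read_fasta_sequences(fasta):
        if found >= n or len(seq) < k:
            continue
        b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        valid = _BASE_INDEX[b] >= 0
        wins = np.lib.stride_tricks.sliding_window_view(b, k)
        ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
        admissible = wins[ok]
        take = min(n - found, len(admissible))
        if take:
            blocks.append(np.ascontiguousarray(admissible[:take]))
            found += take
    if found < n:
        raise ValueError(
            f"only {found} admissible windows available, {n} requested ({n - found} short)"
        )
    a = np.concatenate(blocks, axis=0)
    return _as_output(a, as_array)


def synthetic_genome(
    path: str | Path,
    length: int = DEFAULT_GENOME_LENGTH,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    line_width: int = 70,
) -> Path:
    """Write a single-record synthetic FASTA genome and return its path.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2;
    lines wrap at ``line_width`` columns.  The header records the generating
    parameters, so the file is self-describing and byte-identical under a
    fixed seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = _ALPHABET[rng.choice(4, size=length, p=p)]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">synthetic_genome length={length} gc={gc} seed={seed} [synthetic stand-in for a bacterial chromosome]\n")
        for start in range(0, length, line_width):
            fh.write(bases[start : start + line_width].tobytes().decode("ascii"))
            fh.write("\n")
    return path
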