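"""Bucket-occupancy uniformity (Pearson chi-square) and avalanche measurement.

Uniformity: hash values are reduced to m buckets by ``h mod m`` and the
occupancy vector is scored against the uniform expectation n/m with a
Pearson chi-square test on m - 1 degrees of freedom.  Bucketings whose
expected count n/m is <= 5 are suppressed (the chi-square approximation is
unreliable there).  A panel of bucket counts — powers of two and nearby odd
primes, spanning typical hash-table sizes — is evaluated per dataset and
summarized by the median admissible p value.

Avalanche: for each origin k-mer, single-base mutants are drawn (position
uniform, replacement uniform over the three other bases) and the fraction
of the 32 output bits flipped, popcount(h_orig XOR h_mut)/32, is averaged
over all origin-mutant pairs.  Ideal diffusion gives mean flip = 0.5.

Because a CRC is affine over GF(2), the output XOR under an input XOR-delta
does not depend on the base message; :func:`exact_crc_mean_flip` exploits
this to compute the exact expectation of the mean flip for any CRC
configuration by enumerating the finite set of position x substitution
deltas — the analytic check for the Monte Carlo estimate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as _sps

from .crc import CrcParams, crc32_bytes
from .packing import kmers_to_ascii
from .registry import HashConfig, hash_batch, hash_kmer

__all__ = [
    "DEFAULT_BUCKET_PANEL",
    "UniformityReport",
    "AvalancheReport",
    "bucket_counts",
    "chi2_uniformity",
    "uniformity_panel",
    "mutate_single_base",
    "mutate_batch",
    "avalanche",
    "exact_crc_mean_flip",
]

#: Powers of two and nearby odd primes spanning typical hash-table sizes.
DEFAULT_BUCKET_PANEL = (64, 67, 256, 257, 1021, 1024, 4093, 4096, 16381, 16384, 65521, 65536)

#: Minimum admissible expected count per bucket for the chi-square test.
MIN_EXPECTED = 5.0

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _BASE_INDEX[ord(_c)] = _i
    _BASE_INDEX[ord(_c.lower())] = _i


@dataclass(frozen=True)
class UniformityReport:
    config_label: str
    dataset: str
    m: int
    counts: np.ndarray = field(repr=False)
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = [int(c) for c in self.counts]
        return d


@dataclass(frozen=True)
class AvalancheReport:
    config_label: str
    n_pairs: int
    b: int
    mean_flip: float
    flip_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def bucket_counts(hashes: np.ndarray, m: int) -> np.ndarray:
    """Occupancy vector of length m under ``bucket = h mod m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    h = np.asarray(hashes, dtype=np.uint32)
    return np.bincount(h % np.uint32(m), minlength=m).astype(np.int64)


def chi2_uniformity(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of an occupancy vector against the uniform expectation.

    Returns ``(chi2, df, p)`` with df = m - 1 and p the upper-tail
    probability.  Raises ``ValueError`` when m < 2 or the expected count
    n/m is not > 5 (guarded-out regime).
    """
    c = np.asarray(counts, dtype=np.float64)
    m = c.size
    if m < 2:
        raise ValueError("chi-square needs at least 2 buckets")
    n = c.sum()
    expected = n / m
    if expected <= MIN_EXPECTED:
        raise ValueError(
            f"expected count n/m = {expected:.2f} <= {MIN_EXPECTED}: "
            "chi-square approximation unreliable; bucketing suppressed"
        )
    chi2 = float(((c - expected) ** 2 / expected).sum())
    df = m - 1
    p = float(_sps.chi2.sf(chi2, df))
    return chi2, df, p


def uniformity_panel(
    config: HashConfig,
    kmers: np.ndarray | list[str],
    m_panel: tuple[int, ...] = DEFAULT_BUCKET_PANEL,
    dataset: str = "random",
) -> tuple[list[UniformityReport], float]:
    """One uniformity report per admissible bucket count, plus the median p.

    Bucketings failing the expected-count guard are silently excluded; the
    dataset-level summary is the median of the admissible p values (nan if
    none are admissible).
    """
    hashes = hash_batch(config, kmers)
    n = hashes.size
    reports: list[UniformityReport] = []
    for m in m_panel:
        if m < 2 or n / m <= MIN_EXPECTED:
            continue
        counts = bucket_counts(hashes, m)
        chi2, df, p = chi2_uniformity(counts)
        reports.append(UniformityReport(config.label, dataset, m, counts, chi2, df, p))
    summary = float(np.median([r.p for r in reports])) if reports else float("nan")
    return reports, summary


def mutate_single_base(kmer: str, rng: np.random.Generator) -> str:
    """Single-nucleotide substitution: position uniform over k, new base uniform
    over the three alternatives.  Hamming distance to the input is exactly 1."""
    k = len(kmer)
    if k < 1:
        raise ValueError("empty k-mer")
    pos = int(rng.integers(k))
    old = _BASE_INDEX[ord(kmer[pos])]
    if old < 0:
        raise ValueError(f"invalid nucleotide {kmer[pos]!r} at position {pos}")
    new = (old + int(rng.integers(1, 4))) % 4
    return kmer[:pos] + "ACGT"[new] + kmer[pos + 1 :]


def mutate_batch(ascii_kmers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`mutate_single_base` over an (n, k) uppercase ASCII array."""
    a = np.asarray(ascii_kmers, dtype=np.uint8)
    n, k = a.shape
    pos = rng.integers(k, size=n)
    offset = rng.integers(1, 4, size=n)
    rows = np.arange(n)
    old = _BASE_INDEX[a[rows, pos]]
    if (old < 0).any():
        raise ValueError("non-ACGT base in mutation input")
    out = a.copy()
    out[rows, pos] = _ALPHABET[(old + offset) % 4]
    return out


def avalanche(
    config: HashConfig,
    originals: np.ndarray | list[str],
    mutants_per_origin: int = 3,
    rng: np.random.Generator | int | None = 0,
) -> AvalancheReport:
    """Monte Carlo mean flip of *config* under single-base substitutions.

    Hashes all originals once, then ``mutants_per_origin`` independent
    mutants of each, and averages popcount(XOR)/32 over every pair.
    """
    if mutants_per_origin < 1:
        raise ValueError("mutants_per_origin must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = kmers_to_ascii(originals) if isinstance(originals, (list, tuple)) else np.asarray(originals, dtype=np.uint8)
    h0 = hash_batch(config, a)
    flips = []
    for _ in range(mutants_per_origin):
        hm = hash_batch(config, mutate_batch(a, rng))
        flips.append(np.bitwise_count(h0 ^ hm).astype(np.float64) / 32.0)
    all_flips = np.concatenate(flips)
    return AvalancheReport(
        config_label=config.label,
        n_pairs=int(all_flips.size),
        b=32,
        mean_flip=float(all_flips.mean()),
        flip_sd=float(all_flips.std(ddof=1)),
    )


def exact_crc_mean_flip(params: CrcParams, k: int, preprocessing: str = "gen32") -> float:
    """Exact expected mean flip of a CRC config under the single-base protocol.

    By CRC affine-linearity the flip fraction of an origin-mutant pair
    depends only on the XOR-delta of the two encoded messages, so the
    expectation over uniform origins, uniform positions and uniform
    substitutions is the plain average of popcount/32 over all
    k x 4 x 3 ordered (position, base, replacement) deltas.  Each delta's
    flip count is evaluated on an actual message pair (all-A background),
    which is exact because the background cancels.
    """
    config = HashConfig(preprocessing, "crc32", params=params)
    total = 0.0
    count = 0
    background = "A" * k
    for pos in range(k):
        for old in "ACGT":
            base_seq = background[:pos] + old + background[pos + 1 :]
            h_old = hash_kmer(config, base_seq)
            for new in "ACGT":
                if new == old:
                    continue
                mut_seq = background[:pos] + new + background[pos + 1 :]
                total += bin(h_old ^ hash_kmer(config, mut_seq)).count("1") / 32.0
                count += 1
    return total / count
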