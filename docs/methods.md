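# Methods

## The hashing scheme

A DNA k-mer s = s₀s₁…s_{k−1} over {A,C,G,T} (case-insensitive) is hashed in
two stages.

**gen32 packing.** Each character's ASCII byte is masked with 0x0E. Bits 1–3
of the ASCII codes of A/a, C/c, G/g, T/t are pairwise distinct and identical
across case, so the mask yields the codes A→0x0, C→0x2, G→0x6, T→0x4 with no
explicit case normalization. Codes are packed two per byte — the
even-indexed base in the high nibble, its successor in the low nibble; for
odd k the final lone code occupies the low nibble of the last byte — giving
a ⌈k/2⌉-byte array. On the four-letter alphabet this map is injective for
every fixed k (verified exhaustively for k ≤ 8 in the tests). The mask is
*not* injective outside ACGT, which is why strict alphabet validation is the
default; a permissive flag exists only for benchmarking parity with raw
hashes.

**Reflected CRC32.** The packed bytes are processed by a table-driven
reflected CRC32: polynomial constants are in reversed (LSB-first) form, the
register starts at 0xFFFFFFFF, each byte indexes a 256-entry table on
`(reg XOR byte) & 0xFF` with a `reg >> 8` update, and the final register is
XORed with 0xFFFFFFFF. This is the convention of zlib and Go's `hash/crc32`;
with polynomial 0xEDB88320 the engine is bit-identical to `zlib.crc32`
(tested), and the canonical check values CRC-32("123456789") = 0xCBF43926
and CRC-32C("123456789") = 0xE3069283 hold. The polynomial constants are
interpreted under this single convention with no normalization attempts —
including odd-looking ones such as 0xAD0424F3 or 0xA3000000. The choice is
validated end to end: under it, the audits reproduce the published
collision-onset structure exactly (see below), which would not survive a
register-convention mismatch.

A 20-polynomial candidate panel is carried in `gencrc32.crc.CANDIDATE_POLYS`.
Screening (`screen_polynomials`) retains those whose gen32 composition is
collision-free for all k in 4..k_max; the eight survivors at k_max = 16 are
`COLLISION_FREE_POLYS`. The discovery is empirical — no theory currently
predicts which polynomials survive — so the audit machinery, not the
constant list, is the load-bearing artifact.

## Collision audits

`count_collisions(config, k)` hashes every one of the 4^k k-mers and
reports `collisions = 4^k − distinct`. Enumeration is arithmetic: index i's
base-4 digits (A<C<G<T, most-significant first) are synthesized directly
into packed nibbles or ASCII bytes in chunks of 2^22, so no Python strings
are materialized. Two backends return identical counts (tested against each
other and against a naive per-string dictionary for k ≤ 6):

* **array** (k ≤ 13): materialize all hash values, `np.unique` — at k = 13
  this is 67M × 4 bytes.
* **bitset** (k = 14..16): a 512 MB occupancy bitset over the 2^32 output
  space, streamed chunk-wise, counting first-set events. Memory-bounded at
  the cost of slower scattered writes; only needed for the full-scale claim.

`first_collision_k` scans k ascending and returns the onset — the smallest
k with ≥ 1 collision. `replicate_audit` re-runs the audit with the
processing order shuffled by a seeded permutation; since hashing is
deterministic and distinct-counting is order-free, all replicates must agree
exactly, and `consistent=False` is reported as an error condition rather
than averaged over. k > 16 is refused without `force=True` (pigeonhole:
4^17 > 2^32).

Problem sizes in the default suite: complete-space audits run through
k = 12 (the eight screened polynomials, ≈ 8 × 22M hashes) and onset scans
through their onsets at k ≤ 12. The k = 13..16 audits use the same code
path via the bitset backend and are exposed in the CLI but, being
multi-hour single-CPU runs, are not part of the default suite.

## Uniformity

Hash values are reduced to m buckets by `h mod m` over a panel of bucket
counts spanning typical hash-table sizes — powers of two and nearby odd
primes: {64, 67, 256, 257, 1021, 1024, 4093, 4096, 16381, 16384, 65521,
65536}. Occupancies are scored with Pearson's χ² against the uniform
expectation n/m on df = m − 1, converted to an upper-tail p value
(`scipy.stats.chi2.sf`). Bucketings with expected count n/m ≤ 5 are
suppressed — the χ² approximation is unreliable there — and the guard is
itself tested. Each dataset gets the full per-m table plus a single summary
p; the summary is the **median** of the admissible p values, chosen because
an order statistic is stable against one aberrant bucketing. Any aggregation
rule here is a package design choice; published single-p-per-dataset tables
generally do not state theirs, so per-m values are always emitted alongside.

Three workload regimes, 10^6 k-mers each by default, all hashed from the
identical k-mer list per config under comparison:

* **Random** — every base i.i.d. uniform. Emulates hashing unrelated keys.
* **Similar** — a chain where element i+1 is a single-base edit of element
  i (position uniform, replacement uniform over the other three bases;
  duplicates permitted — it is a workload, not a key set). Emulates
  localized-edit traffic such as variant neighborhoods.
* **Window** — step-1 sliding windows over a genome FASTA, windows with
  non-ACGT characters skipped, first n admissible windows taken, forward
  strand only, never spanning record boundaries. The default source is a
  synthetic genome: 4.6 Mb, GC 0.508, i.i.d. bases — the length and GC of
  the *E. coli* K-12 chromosome, so no download is required. An i.i.d.
  sequence has no repeats, skew or codon structure, so window-regime
  results on it demonstrate the machinery and the broad behavior, not
  fidelity to any particular genome; `--fasta` accepts a real reference
  for fidelity runs.

## Avalanche

For each origin k-mer, three independent single-base mutants are drawn
(position uniform over k, replacement uniform over the three alternatives —
Hamming distance exactly 1 by construction). The statistic is the mean
flip: popcount(h_orig ⊕ h_mut)/b averaged over all origin–mutant pairs,
with b = 32; 0.5 is ideal diffusion.

Because a CRC is affine over GF(2), h(x) ⊕ h(y) for equal-length inputs
depends only on x ⊕ y. The XOR-delta of two encodings differing at one base
is supported on a single nibble (gen32) or byte (raw ASCII), so the exact
expectation of the mean flip is the plain average of popcount/32 over the
k × 4 × 3 ordered (position, base, replacement) deltas —
`exact_crc_mean_flip` computes it by hashing actual message pairs on an
all-A background, which is exact because the background cancels. The Monte
Carlo estimator is required to agree with this value within sampling error
(3 standard errors in tests; 5 in the acceptance script, which then reports
the Monte Carlo value). For the non-linear families (MurmurHash3, xxHash32)
no closed form exists and only the Monte Carlo estimate is reported.

At k = 16 the exact values for the screened CRC configurations fall in
0.45–0.51 depending on polynomial and preprocessing — genuinely
polynomial-dependent, not sampling noise; e.g. gen32+CRC32(0x8741C726)
gives 0.4844, raw CRC32(0x8741C726) 0.5026, gen32+CRC32(0x8EFD4BCD) 0.4544.

## Randomness and reproducibility

All stochastic steps (dataset generation, mutant draws, replicate
shuffling) flow from explicit `numpy.random.default_rng` seeds recorded in
outputs; audits and screens are fully deterministic. `run_benchmark` writes
a manifest capturing every parameter and seed, sufficient to reproduce
audit tables byte-identically. Collision counts are exact set-cardinality
computations — there is no tolerance anywhere in the audit path.

## Numerical and implementation choices

* Hashing is vectorized column-wise over `(n, L)` uint8 numpy arrays
  (one table lookup per byte position for CRC; unrolled block rounds for
  MurmurHash3/xxHash32, which wrap modulo 2^32 via uint32 arithmetic).
  Scalar and vectorized paths are tested against each other at every tail
  length.
* MurmurHash3-32 and xxHash32 are implemented from their public
  specifications; murmur is additionally cross-checked against
  scikit-learn's `murmurhash3_32`, and both are pinned to canonical
  published check values. Seeds default to 0 and are recorded in config
  labels, since collision onsets of non-linear hashes are seed-dependent.
* Raw-mode hashing uppercases the ASCII input first so raw and gen32 modes
  see the same logical k-mer set; enumerated spaces are generated uppercase,
  so this is a neutral normalization.
* Chunk size defaults to 2^22 items (< 64 MB per intermediate block);
  results are chunk-size invariant (tested).
* Throughput is wall-clock hashes/second over a warm run. It is reported
  for context only and never compared across machines or implementations —
  absolute speed reflects language and vectorization strategy at least as
  much as the algorithm.

## Known limitations

* The collision-free property is an audited empirical fact for k ≤ 16 under
  exactly this convention (reversed polynomial, init/xor-out 0xFFFFFFFF);
  it does not transfer to other CRC conventions, other polynomials, or
  k > 16 (impossible in 32 bits by pigeonhole).
* No reverse-complement canonicalization: a k-mer and its reverse
  complement hash independently. Canonicalizing callers must do so before
  hashing.
* The 2-bit rolling encoding (an alternative injective representation
  supporting O(1) sliding updates) is deliberately out of scope.
* The default test suite proves injectivity through k = 12; k = 13..16 use
  the identical audited code path but must be run explicitly.
* The synthetic genome is an i.i.d. stand-in; window-regime p values on
  real genomes (with repeats and skew) may differ.
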