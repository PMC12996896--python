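# gencrc32

Collision-free 32-bit hashing of DNA k-mers, with the evaluation battery to
prove it.

## The problem

Hash tables are the workhorse behind k-mer indices, de Bruijn graph
assemblers and metagenomic classifiers. A 32-bit hash space can in principle
hold all 4^k k-mers up to k = 16 (4^16 ≈ 2^32), but general-purpose hashes
(MurmurHash3, xxHash32, off-the-shelf CRC32) start colliding long before
that, and every collision is a potential mis-assembly, spurious match or
lost count. Minimal perfect hash functions avoid collisions but only for one
fixed key set. This package implements and audits a *general-purpose*
collision-free scheme for all k ≤ 16:

1. **gen32 packing** — each nucleotide's ASCII byte is masked with `0x0E`,
   which isolates the three bits that distinguish A/C/G/T and is identical
   for upper and lower case (`A→0x0, C→0x2, G→0x6, T→0x4`); two 4-bit codes
   are packed per byte, turning a k-mer into ⌈k/2⌉ bytes.
2. **Reflected CRC32** — the packed bytes are hashed by a table-driven
   reflected CRC32 (reversed-form polynomial, `init = xor_out = 0xFFFFFFFF`,
   the zlib/Go convention) with a polynomial drawn from a screened panel.

Eight reversed-form polynomials — `0x8741C726, 0x87496166, 0x8E2371EF,
0x8EE5368F, 0x8EFD4BCD, 0x945D045D, 0x9D9947FD, 0xEB31D82E` — make this
composition injective on every complete 4^k space up to k = 16. The package
ships the scheme itself plus everything needed to verify and characterize
it: exhaustive collision audits over complete 4^k spaces, polynomial
screening, Pearson χ² bucket-occupancy uniformity (df = m−1, expected-count
> 5 guard), and avalanche measurement (mean flipped-bit fraction under
single-base substitutions; 0.5 is ideal diffusion).

It is intended for bioinformatics tool authors choosing a k-mer hashing
primitive, and for anyone who wants to re-verify the collision-free claim
rather than take it on faith.

## Worked example

```sh
$ gencrc32 hash --config gen32+crc32:0x8741C726 ACGTACGTACGTACGT acgtacgtacgtacgt TCGTACGTACGTACGT
ACGTACGTACGTACGT        0x28F05414
acgtacgtacgtacgt        0x28F05414
TCGTACGTACGTACGT        0x7C337C6C
```

Case variants hash identically (the 0x0E mask never sees case), and a
single-base change rewrites roughly half the output bits. Collision onsets
are found by exhaustive scan over complete k-mer spaces:

```sh
$ gencrc32 scan --config none+murmur3_32:0 --kmin 4 --kmax 10
config_label        k_min   k_max   first_collision_k
none+murmur3_32:0   4       10      9
```

Raw MurmurHash3 first collides at k = 9 (all 4^9 = 262,144 9-mers hashed,
fewer than 262,144 distinct values) — whereas `gen32+crc32:0x8741C726`
yields zero collisions at every k up to 16. Avalanche behavior:

```sh
$ gencrc32 avalanche --config gen32+crc32:0x8741C726 --n 100000 --k 16 --mutants 3 --seed 1
config_label                n_pairs  b   mean_flip  flip_sd  seed
gen32+crc32:0x8741C726      300000   32  0.4843     0.0734   1
```

On average 48.4% of the 32 output bits flip per single-base substitution,
close to the ideal 0.5. Because a CRC is affine over GF(2), this number has
an exact closed form (`gencrc32.exact_crc_mean_flip`), which the Monte Carlo
estimate matches to within sampling error.

Other verbs: `audit` (exact collision count at one k, with shuffled-order
replicates), `screen` (filter a polynomial panel), `uniformity` (χ² bucket
panel over the Random / Similar / Window workload regimes), `datasets`
(workload generators, including a synthetic bacterial-scale genome so the
sliding-window regime needs no download), and `bench` (full grid with a
reproducibility manifest). The same functionality is available as a library
(`import gencrc32`).

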