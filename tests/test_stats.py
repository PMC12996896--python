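"""Uniformity (chi-square) and avalanche measurement."""

import numpy as np
import pytest

from gencrc32.crc import CrcParams
from gencrc32.registry import HashConfig, register_family
from gencrc32.stats import (
    DEFAULT_BUCKET_PANEL,
    avalanche,
    bucket_counts,
    chi2_uniformity,
    exact_crc_mean_flip,
    mutate_batch,
    mutate_single_base,
    uniformity_panel,
)


def test_bucket_counts_examples(rng):
    assert list(bucket_counts(np.array([0, 1, 2, 3]), 2)) == [2, 2]
    h = rng.integers(0, 2**32, size=1000, dtype=np.uint32)
    assert list(bucket_counts(h, 1)) == [1000]
    perm = rng.permutation(1000)
    assert np.array_equal(bucket_counts(h, 67), bucket_counts(h[perm], 67))
    assert bucket_counts(h, 67).sum() == 1000
    with pytest.raises(ValueError):
        bucket_counts(h, 0)


@pytest.mark.parametrize(
    "counts,chi2,p",
    [([8, 8], 0.0, 1.0), ([10, 6], 1.0, 0.31731), ([12, 4], 4.0, 0.04550)],
)
def test_chi2_hand_values(counts, chi2, p):
    """Pearson statistic and upper-tail p against the hand formula."""
    stat, df, pval = chi2_uniformity(counts)
    assert stat == pytest.approx(chi2, abs=1e-12)
    assert df == 1
    assert pval == pytest.approx(p, abs=5e-5)


def test_chi2_guard_expected_must_exceed_five():
    with pytest.raises(ValueError, match="unreliable"):
        chi2_uniformity([5, 5])  # expected = 5, not > 5
    with pytest.raises(ValueError):
        chi2_uniformity([10])


def test_uniformity_panel_applies_guard(gen32_crc_config, rng):
    """n=10,000 excludes every m with n/m <= 5 (here m >= 2000); no report violates the guard."""
    from gencrc32.datasets import random_kmers

    kmers = random_kmers(10_000, 8, seed=rng, as_array=True)
    reports, summary = uniformity_panel(gen32_crc_config, kmers)
    assert {r.m for r in reports} == {m for m in DEFAULT_BUCKET_PANEL if 10_000 / m > 5}
    for r in reports:
        assert r.df == r.m - 1
        assert 0.0 <= r.p <= 1.0
        assert r.counts.sum() == 10_000
    assert summary == pytest.approx(float(np.median([r.p for r in reports])))


def test_uniformity_panel_deterministic(gen32_crc_config):
    from gencrc32.datasets import random_kmers

    kmers = random_kmers(5_000, 8, seed=3, as_array=True)
    r1, s1 = uniformity_panel(gen32_crc_config, kmers)
    r2, s2 = uniformity_panel(gen32_crc_config, kmers)
    assert s1 == s2
    assert all(a.chi2 == b.chi2 for a, b in zip(r1, r2))


def test_chi2_null_behavior_on_uniform_integers():
    """Uniform random 32-bit integers (not hashes) are not systematically
    rejected: across seeds, alpha=0.01 rejections stay near the nominal rate."""
    rejections = 0
    for seed in range(20):
        h = np.random.default_rng(seed).integers(0, 2**32, size=50_000, dtype=np.uint32)
        _, _, p = chi2_uniformity(bucket_counts(h, 1024))
        rejections += p < 0.01
    assert rejections <= 2


def test_mutate_single_base_properties(rng):
    for _ in range(200):
        kmer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12))
        mut = mutate_single_base(kmer, rng)
        assert sum(a != b for a, b in zip(kmer, mut)) == 1
    r1 = mutate_single_base("ACGTACGT", np.random.default_rng(5))
    r2 = mutate_single_base("ACGTACGT", np.random.default_rng(5))
    assert r1 == r2


def test_mutation_position_uniform(rng):
    """Over 10,000 draws on 'AAAA' each position is hit ~2,500 times (3 sigma)."""
    a = np.frombuffer(b"AAAA" * 10_000, dtype=np.uint8).reshape(10_000, 4)
    mut = mutate_batch(a, rng)
    hits = (mut != a).sum(axis=0)
    assert (mut != a).sum() == 10_000  # exactly one change per row
    sigma = np.sqrt(10_000 * 0.25 * 0.75)
    assert np.all(np.abs(hits - 2500) < 3 * sigma)


def test_avalanche_extremes():
    """A constant hash flips nothing; a bit-inverting pair flips everything."""
    register_family("testzero32", lambda data, seed: 0)
    cfg = HashConfig("none", "testzero32")
    from gencrc32.datasets import random_kmers

    rep = avalanche(cfg, random_kmers(100, 8, seed=1, as_array=True), 2, rng=0)
    assert rep.mean_flip == 0.0 and rep.n_pairs == 200 and rep.b == 32
    assert bin(0x00000000 ^ 0xFFFFFFFF).count("1") / 32 == 1.0


def test_avalanche_monte_carlo_matches_exact_linearity_value(gen32_crc_config):
    """The Monte Carlo mean flip converges on the exact delta-enumeration value."""
    from gencrc32.datasets import random_kmers

    exact = exact_crc_mean_flip(gen32_crc_config.params, 10, "gen32")
    origins = random_kmers(20_000, 10, seed=2, as_array=True)
    rep = avalanche(gen32_crc_config, origins, 3, rng=2)
    se = rep.flip_sd / np.sqrt(rep.n_pairs)
    assert abs(rep.mean_flip - exact) < 3 * se + 1e-9


def test_exact_mean_flip_background_independent():
    """Affine linearity: the exact value is the same whatever the construction
    background, checked by direct Monte Carlo on a tiny space."""
    params = CrcParams(0xD2C0EF07)
    exact = exact_crc_mean_flip(params, 4, "none")
    cfg = HashConfig("none", "crc32", params=params)
    from gencrc32.datasets import random_kmers

    rep = avalanche(cfg, random_kmers(30_000, 4, seed=9, as_array=True), 2, rng=9)
    assert rep.mean_flip == pytest.approx(exact, abs=3 * rep.flip_sd / np.sqrt(rep.n_pairs))
    assert 0.0 <= exact <= 1.0
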