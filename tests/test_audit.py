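"""Collision audits: exactness, backend equivalence, replicates, screening."""

import numpy as np
import pytest

from gencrc32.audit import (
    count_collisions,
    first_collision_k,
    replicate_audit,
    screen_polynomials,
)
from gencrc32.crc import CANDIDATE_POLYS, CrcParams
from gencrc32.kmerspace import index_to_kmer, total_kmers
from gencrc32.registry import HashConfig, hash_kmer


@pytest.mark.parametrize(
    "config",
    [
        HashConfig.crc(0x8741C726, "gen32"),
        HashConfig.crc(0xD2C0EF07, "none"),
        HashConfig("none", "murmur3_32"),
        HashConfig("gen32", "xxhash32"),
    ],
    ids=lambda c: c.label,
)
@pytest.mark.parametrize("k", [5, 6])
def test_distinct_count_matches_naive_dictionary(config, k):
    """The vectorized audit equals a per-string dictionary built from ASCII k-mers."""
    naive = {hash_kmer(config, index_to_kmer(i, k)) for i in range(total_kmers(k))}
    rep = count_collisions(config, k)
    assert rep.distinct == len(naive)
    assert rep.collisions == rep.total - rep.distinct
    assert rep.total == total_kmers(k)


def test_injective_config_at_k4_has_256_distinct(gen32_crc_config):
    rep = count_collisions(gen32_crc_config, 4)
    assert rep.distinct == 256 and rep.collisions == 0


@pytest.mark.parametrize(
    "config",
    [HashConfig.crc(0x8741C726, "gen32"), HashConfig("none", "murmur3_32")],
    ids=lambda c: c.label,
)
@pytest.mark.parametrize("k", [6, 8])
def test_backend_equivalence(config, k):
    """Sort-unique and 2^32-bitset backends return identical distinct counts."""
    a = count_collisions(config, k, backend="array")
    b = count_collisions(config, k, backend="bitset")
    assert a.distinct == b.distinct


@pytest.mark.parametrize("chunk", [100, 4096, 1 << 22])
def test_chunk_size_invariance(gen32_crc_config, chunk):
    rep = count_collisions(gen32_crc_config, 6, chunk=chunk)
    assert rep.distinct == total_kmers(6)


def test_k_beyond_injectivity_limit_refused(gen32_crc_config):
    with pytest.raises(ValueError, match="force"):
        count_collisions(gen32_crc_config, 17)


def test_k_outside_usual_range_warns(gen32_crc_config):
    with pytest.warns(UserWarning):
        count_collisions(gen32_crc_config, 3)


def test_replicate_audit_consistent_and_matches_single_run(gen32_crc_config):
    """Shuffled processing order never changes the distinct count."""
    single = count_collisions(gen32_crc_config, 8)
    rep = replicate_audit(gen32_crc_config, 8, reps=3, order_seed=7)
    assert rep.consistent
    assert rep.collisions == single.collisions == 0
    assert rep.replicates == 3
    one = replicate_audit(gen32_crc_config, 6, reps=1)
    assert one.distinct == count_collisions(gen32_crc_config, 6).distinct


def test_colliding_config_replicates_agree():
    cfg = HashConfig("none", "murmur3_32")
    rep = replicate_audit(cfg, 9, reps=2, order_seed=1)
    assert rep.consistent and rep.collisions >= 1
    assert rep.collisions == count_collisions(cfg, 9).collisions


def test_first_collision_k_scan_semantics(gen32_crc_config):
    assert first_collision_k(HashConfig("none", "murmur3_32"), 4, 10) == 9
    # onset implies all smaller k collision-free
    assert first_collision_k(gen32_crc_config, 4, 9) is None
    with pytest.raises(ValueError):
        first_collision_k(gen32_crc_config, 8, 4)


def test_screen_preserves_order_and_accepts_ints():
    """At k_max=4 every candidate survives (all onsets are >= 5)."""
    survivors = screen_polynomials(list(CANDIDATE_POLYS), 4)
    assert [p.poly_reversed for p in survivors] == list(CANDIDATE_POLYS)
    assert screen_polynomials([CrcParams(0x8741C726)], 6) == [CrcParams(0x8741C726)]
    with pytest.raises(ValueError):
        screen_polynomials([], 4)


def test_screen_drops_colliding_candidate():
    # raw-onset is irrelevant: screening is on the gen32 variant, and
    # 0x82F63B78's gen32 onset (12) is beyond this k_max, so both survive
    survivors = screen_polynomials([0x82F63B78, 0x8741C726], 8)
    assert [p.poly_reversed for p in survivors] == [0x82F63B78, 0x8741C726]


def test_report_serialization(gen32_crc_config):
    d = count_collisions(gen32_crc_config, 4).to_dict()
    assert d["config_label"] == gen32_crc_config.label
    assert d["total"] == 256 and d["collisions"] == 0
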