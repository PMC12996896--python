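import numpy as np
import pytest
from hypothesis import settings

from gencrc32 import CrcParams, HashConfig

# Deterministic property tests: fixed example order, no on-disk example database.
settings.register_profile("det", deadline=None, derandomize=True, database=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gen32_crc_config():
    """A known-injective scheme: gen32 packing + CRC32(0x8741C726)."""
    return HashConfig.crc(0x8741C726, "gen32")


@pytest.fixture
def raw_crc_config():
    return HashConfig.crc(0xEDB88320, "none")


def random_bytes(rng: np.random.Generator, length: int) -> bytes:
    return rng.integers(0, 256, size=length, dtype=np.uint8).tobytes()
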