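import numpy as np
import pytest

from oligocode.channel import ChannelParams, sample_reads
from oligocode.codec import CodeParams, encode_file


@pytest.fixture(scope="session")
def small_params():
    """A small outer code (shortened to N=255) for fast roundtrip tests."""
    return CodeParams(n_oligos=255, k_oligos=171)


@pytest.fixture(scope="session")
def small_file():
    return np.random.default_rng(0).integers(0, 256, 1500, dtype=np.uint8).tobytes()


@pytest.fixture(scope="session")
def small_oligos(small_params, small_file):
    return encode_file(small_file, small_params)


@pytest.fixture(scope="session")
def small_reads(small_oligos):
    """Simulated read pool at the default channel settings, coverage 30."""
    return sample_reads(small_oligos, ChannelParams(seed=3), coverage=30)
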