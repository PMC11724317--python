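import numpy as np
import pytest

from duplexkit import cli_io
from duplexkit.synthetic_data import ConformerTruth, gen_duplex_frames


@pytest.fixture(scope="session")
def table1():
    return cli_io.load_table1()


@pytest.fixture(scope="session")
def table2():
    return cli_io.load_table2()


@pytest.fixture(scope="session")
def clean_frames():
    """Ten zero-jitter frames, 70/30 anti-anti / syn-anti."""
    truth = ConformerTruth(jitter_sd=0.0, seed=1)
    fs, labels = gen_duplex_frames(truth, 10)
    return truth, fs, labels


@pytest.fixture(scope="session")
def jittered_frames():
    """300 frames at the default 0.05 A jitter, 70/30 two-state mixture."""
    truth = ConformerTruth(jitter_sd=0.05, seed=7)
    fs, labels = gen_duplex_frames(truth, 300)
    return truth, fs, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
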