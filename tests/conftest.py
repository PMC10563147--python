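import numpy as np
import pytest

from ogmap import (
    ChannelModel,
    PatternSet,
    bin_genome,
    default_table1,
    generate_random_genome,
)


@pytest.fixture(scope="session")
def table1() -> ChannelModel:
    return default_table1()


@pytest.fixture(scope="session")
def identity_channel() -> ChannelModel:
    """Noiseless channel with uniform inputs over 3 symbols."""
    return ChannelModel(cap=2, p_x=np.full(3, 1 / 3), p_y_given_x=np.eye(3))


@pytest.fixture(scope="session")
def independent_channel() -> ChannelModel:
    """y carries no information about x: all likelihood rows equal."""
    row = np.array([0.5, 0.3, 0.2])
    return ChannelModel(cap=2, p_x=np.array([0.6, 0.3, 0.1]), p_y_given_x=np.tile(row, (3, 1)))


@pytest.fixture(scope="session")
def small_genome():
    """1-Mb seeded random genome (1000 bins at 1 kb)."""
    return generate_random_genome(10**6, seed=42)


@pytest.fixture(scope="session")
def small_binned(small_genome):
    return bin_genome(small_genome, PatternSet.from_string("CTTAAG"), 1000, 2)


@pytest.fixture()
def fasta_file(tmp_path):
    def write(text: str, name: str = "g.fa"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
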