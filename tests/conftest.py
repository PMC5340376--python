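import numpy as np
import pytest

from mtphylogeo.seqio import Alignment, Dataset, PopulationMap
from mtphylogeo.synthetic_data import SimulationConfig, simulate_dataset_object


@pytest.fixture
def toy_alignment() -> Alignment:
    """4 sequences over 2 segregating sites: patterns (A,A,A,T), (A,A,T,T)."""
    return Alignment(("s1", "s2", "s3", "s4"), ("AA", "AA", "AT", "TT"))


@pytest.fixture
def toy_dataset(toy_alignment) -> Dataset:
    popmap = PopulationMap({"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"})
    return Dataset(toy_alignment, popmap)


def two_pop_fixed_dataset() -> Dataset:
    """Each population fixed for its own haplotype (between-pop distance 2)."""
    aln = Alignment(("a1", "a2", "a3", "b1", "b2", "b3"),
                    ("AAAA",) * 3 + ("AATT",) * 3)
    popmap = PopulationMap({f"a{i}": "PA" for i in range(1, 4)}
                           | {f"b{i}": "PB" for i in range(1, 4)})
    return Dataset(aln, popmap)


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset shared across the session."""
    return simulate_dataset_object(SimulationConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
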