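import numpy as np
import pytest

from acrstack import (
    EmbeddingMatrix,
    ProteinRecord,
    PSSMProfile,
    SimulationConfig,
    simulate_dataset,
)
from acrstack.records import AMINO_ACIDS


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_pssm(rng: np.random.Generator, length: int, record_id: str = "p") -> PSSMProfile:
    matrix = rng.integers(-5, 10, size=(length, 20)).astype(float)
    return PSSMProfile(record_id, matrix, random_sequence(rng, length))


def random_embedding(rng: np.random.Generator, length: int, dim: int,
                     record_id: str = "e") -> EmbeddingMatrix:
    return EmbeddingMatrix(record_id, rng.standard_normal((length, dim)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_record():
    return ProteinRecord("m", "MKVLA")


@pytest.fixture(scope="session")
def small_dataset():
    """A small separable corpus shared by io/model tests."""
    cfg = SimulationConfig(
        n_pos=12, n_neg=12, length_range=(30, 60), effect=2.0, seed=11
    )
    return simulate_dataset(cfg)
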