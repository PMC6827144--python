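import numpy as np
import pytest

from zcmm.seqio import DnaSequence, Label, SequenceSet

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, id: str = "seq") -> DnaSequence:
    return DnaSequence(id, "".join(BASES[i] for i in rng.integers(0, 4, size=length)))


def random_set(
    rng: np.random.Generator, n: int, length: int, label=Label.UNLABELED
) -> SequenceSet:
    return SequenceSet(
        tuple(random_seq(rng, length, f"s{i}") for i in range(n)), label=label
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_set(rng) -> SequenceSet:
    return random_set(rng, 8, 30)


@pytest.fixture
def tiny_dataset():
    """A small well-separated two-class dataset for pipeline tests."""
    from zcmm.synthetic import GeneratorSpec, generate_dataset

    return generate_dataset(GeneratorSpec(n_per_class=60, length=60, seed=101))
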