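import numpy as np
import pytest

from clpmi.io import Dataset, SequenceRecord
from clpmi.synth import SyntheticParams, make_dataset


@pytest.fixture
def toy_dataset() -> Dataset:
    """Five tiny hand-written records, three labeled."""
    return Dataset(
        [
            SequenceRecord("h1", "GGGAAACCC", structure="(((...)))", label=1),
            SequenceRecord("h2", "GGGGAAAACCCC", structure="((((....))))", label=1),
            SequenceRecord("n1", "ACGUACGUA", structure=".........", label=0),
            SequenceRecord("n2", "AAAAAAAAAA", structure=".........."),
            SequenceRecord("n3", "ACGU", structure="...."),
        ]
    )


@pytest.fixture(scope="session")
def small_synthetic() -> Dataset:
    """Seeded hairpin/decoy dataset shared across training smoke tests."""
    return make_dataset(
        SyntheticParams(n_pos=24, n_neg=96, mutation_rate=0.0, seed=7)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
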