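import numpy as np
import pytest

import abclass


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_peptides(rng):
    """100 random peptides over the standard alphabet, lengths 5-50."""
    aas = np.array(list(abclass.AMINO_ACIDS))
    peptides = []
    for _ in range(100):
        length = int(rng.integers(5, 51))
        peptides.append("".join(rng.choice(aas, size=length)))
    return peptides


@pytest.fixture(scope="session")
def small_dataset():
    """Learnable synthetic dataset, ~215 records over the 11 combinations."""
    return abclass.generate(
        abclass.default_spec(scale=0.02, signal_strength=1.5, seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Smoke-scale dataset (~110 records), moderate signal."""
    return abclass.generate(abclass.default_spec(scale=0.01, seed=3))
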