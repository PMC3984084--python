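import numpy as np
import pytest

from tandemscan.synthetic import generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """One default scenario shared across the suite (seed fixed)."""
    return generate_scenario(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140411)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
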