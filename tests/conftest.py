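import numpy as np
import pytest

from sdrna.simulate import make_reference

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20120810)


@pytest.fixture(scope="session")
def small_reference():
    """Scaled-down synthetic genome shared by read-classification tests."""
    return make_reference(
        seed=11,
        sizes={
            "spacer": 300,
            "18S": 500,
            "5.8S": 157,
            "28S": 800,
            "12S": 400,
            "16S": 500,
            "n_genes": 8,
        },
    )
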