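import numpy as np
import pytest

from replifin.seqmodel import Replicon

HIGH_GC = np.array([0.15, 0.35, 0.35, 0.15])


def random_seq(rng: np.random.Generator, n: int, p=HIGH_GC) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    """A 30 kb high-GC replicon for alignment-level tests."""
    return Replicon("g", random_seq(rng, 30_000))
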