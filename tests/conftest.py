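import numpy as np
import pytest

from arraychrom import GenomeConfig, build_genome
from arraychrom.tracks import FragmentSet, StrandedCoverage


@pytest.fixture(scope="session")
def small_genome():
    """2 arrays x 10 repeats, 20 operons: the default synthetic chromosome."""
    return build_genome(GenomeConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_fragments(rng):
    """2e5 fragments with integer lengths uniform on [40, 300] bp."""
    n = 200_000
    lengths = rng.integers(40, 301, size=n)
    starts = rng.integers(0, 10_000, size=n)
    return FragmentSet("chr", starts, starts + lengths)


def make_coverage(length, plus=(), minus=(), replicon="chr", circular=True):
    """Build a StrandedCoverage from sparse (pos, count) pairs."""
    fwd = np.zeros(length)
    rev = np.zeros(length)
    for pos, count in plus:
        fwd[pos] = count
    for pos, count in minus:
        rev[pos] = count
    return StrandedCoverage(replicon, fwd, rev, circular)
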