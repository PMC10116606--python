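import numpy as np
import pytest

from paintscan import scenarios
from paintscan.simulate import HaplotypeTractSet, RecombinationMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_model():
    """A cheap demography for plumbing tests (not the study conditions)."""
    return scenarios.baseline_model(N0=100, generations=5, length=5e6)


@pytest.fixture(scope="session")
def uniform_map():
    return RecombinationMap(length=50e6, rate=1.3e-8)


def make_haplotype(ends, anc, length=None, alleles=None):
    """Single-chromosome haplotype from plain lists."""
    hap = HaplotypeTractSet(
        [(np.asarray(ends, dtype=float), np.asarray(anc, dtype=np.int8))],
        np.asarray(alleles, dtype=np.int8) if alleles is not None else None,
    )
    if length is not None:
        hap.validate([length])
    return hap
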