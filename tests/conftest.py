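import numpy as np
import pytest

from gwaspower import GeneticArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def arch_fig1():
    """Architecture used throughout the worked examples (h2=0.7, pi0=0.9)."""
    return GeneticArchitecture(h2=0.7, pi0=0.9, m=60_000)


@pytest.fixture
def arch_moderate():
    return GeneticArchitecture(h2=0.4, pi0=0.99, m=60_000)
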