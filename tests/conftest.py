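import numpy as np
import pytest

from phagesim.core import PhageGenotype, build_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def temperate():
    return PhageGenotype(name="phi", lifestyle="temperate", p_gt=0.1, burst_size=50)


@pytest.fixture
def virulent():
    return PhageGenotype(name="phiV", lifestyle="virulent", p_gt=0.1, burst_size=50)


@pytest.fixture
def donor_genome():
    """100-slot genome with one active CAM resistance gene at locus 50."""
    return build_genome("donor", size=100, markers=(("CAM", True, 50),))


@pytest.fixture
def recipient_genome():
    """100-slot genome with an inactive (silent) CAM resistance gene."""
    return build_genome("recipient", size=100, markers=(("CAM", False, 50),))
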