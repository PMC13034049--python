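import numpy as np
import pytest

from coacervmd import constructs as cx
from coacervmd import forcefield as ff


@pytest.fixture(scope="session")
def library():
    """The canonical molecule set, one deterministic instance per session."""
    return cx.canonical_constructs(seed=7)


@pytest.fixture(scope="session")
def ffconfig():
    return ff.ForceFieldConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def relaxed_chain_coords(c, ffc, rng, jitter=0.3):
    """Near-ideal coordinates for a construct with small random jitter
    (keeps bonded terms finite and beads non-overlapping)."""
    from coacervmd.simulator import template_coords

    x = template_coords(c, ffc, rng)
    return x + jitter * rng.standard_normal(x.shape)
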