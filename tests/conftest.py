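import numpy as np
import pytest

from cpinet import synthetic


@pytest.fixture(scope="session")
def tiny_targets():
    """Four synthetic targets (two site-capable, two not), fixed seed."""
    return synthetic.generate_targets(4, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_targets):
    """Pairs + featurizable inputs for the tiny target set."""
    pairs, molecules, manifest = synthetic.generate_pairs(
        tiny_targets, molecules_per_target=8, ratio=1, seed=7
    )
    return pairs, molecules, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
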