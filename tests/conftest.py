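import numpy as np
import pytest

import gcirnet as g


@pytest.fixture(scope="session")
def montage8():
    """8-channel sensorimotor fixture montage."""
    return g.default_montage8()


@pytest.fixture(scope="session")
def montage64():
    return g.load_montage("standard_10_10_64")


@pytest.fixture(scope="session")
def binary_trialset(montage8):
    """Small binary synthetic set with strong lateralized mu/beta sources."""
    ts, truth = g.simulate_trials(
        g.SynthConfig.binary_lateralized(n_per_class=20, seed=11), montage8
    )
    return ts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
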