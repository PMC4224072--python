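import numpy as np
import pytest

from biletox.hepatotox import default_injury_params, default_tox_params
from biletox.physiology import load_physiology


@pytest.fixture(scope="session")
def human():
    physiology, transporters = load_physiology("human")
    return physiology, transporters


@pytest.fixture(scope="session")
def rat():
    physiology, transporters = load_physiology("rat")
    return physiology, transporters


@pytest.fixture(scope="session")
def human_tox(human):
    return default_tox_params(human[0])


@pytest.fixture(scope="session")
def human_injury(human):
    return default_injury_params(human[0])


@pytest.fixture(scope="session")
def human_baseline():
    """Solved drug-free baseline of the unperturbed human (cached globally)."""
    from biletox.scenarios import baseline_context

    return baseline_context("human")


@pytest.fixture(scope="session")
def rat_baseline():
    from biletox.scenarios import baseline_context

    return baseline_context("rat")


@pytest.fixture
def rng():
    return np.random.default_rng(20140240)
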