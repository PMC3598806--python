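import numpy as np
import pytest

from tnswitch.synthetic import ToyLobeSpec, build_beta_hairpin, build_toy_two_state_lobe


@pytest.fixture(scope="session")
def open_lobe():
    return build_toy_two_state_lobe(ToyLobeSpec("open"))


@pytest.fixture(scope="session")
def closed_lobe():
    return build_toy_two_state_lobe(ToyLobeSpec("closed"))


@pytest.fixture(scope="session")
def semi_closed_lobe():
    return build_toy_two_state_lobe(ToyLobeSpec("semi-closed"))


@pytest.fixture(scope="session")
def hairpin():
    return build_beta_hairpin()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
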