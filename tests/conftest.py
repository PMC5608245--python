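import numpy as np
import pytest

from petsae.pipeline import generate_fixture


@pytest.fixture(scope="session")
def toy_projector():
    return generate_fixture("toy-projector")


@pytest.fixture(scope="session")
def tiny_rbm():
    return generate_fixture("tiny-rbm", seed=0)


@pytest.fixture(scope="session")
def gradcheck_net():
    return generate_fixture("gradcheck-net", seed=1)


@pytest.fixture(scope="session")
def mini_phantom():
    return generate_fixture("mini-phantom", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
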