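import numpy as np
import pytest

from renalus import PCNNParams, PhantomSpec, make_phantom


@pytest.fixture
def default_params() -> PCNNParams:
    return PCNNParams()


@pytest.fixture
def uncoupled_params() -> PCNNParams:
    """Linking disabled: every neuron follows the scalar recurrence."""
    return PCNNParams(alpha=0.0)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def phantom(phantom_spec) -> np.ndarray:
    return make_phantom(phantom_spec)


def random_image(rng: np.random.Generator, shape=(8, 8), levels=256) -> np.ndarray:
    return rng.integers(0, levels, size=shape).astype(np.uint8)
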