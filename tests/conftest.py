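import numpy as np
import pytest

from braincube.synthetic import SyntheticSpec, generate_dataset
from braincube.template import ConnectivityConfig, build_template, init_connectivity


@pytest.fixture(scope="session")
def default_template():
    """The full 3108-neuron procedural template (built once per session)."""
    return build_template(3108, seed=0)


@pytest.fixture(scope="session")
def small_template():
    """A 400-neuron template: fast, still populates all region boxes."""
    return build_template(400, seed=1)


@pytest.fixture(scope="session")
def small_cube(small_template):
    return init_connectivity(small_template, ConnectivityConfig(seed=2))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six short multimodal samples for plumbing tests."""
    spec = SyntheticSpec(n_samples_per_class=3, duration_steps=80, seed=42)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
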