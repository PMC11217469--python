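import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_model():
    """The full-size calibrated model (shared: construction is not free)."""
    from gcanet import ModelConfig, build_model

    return build_model(ModelConfig())


@pytest.fixture(scope="session")
def tiny_two_class_data():
    """Small strong-contrast two-class synthetic set used across suites."""
    from gcanet.synthetic import generate_dataset, two_class_spec

    spec = two_class_spec(n_per_class=16, image_size=64, seed=1)
    return generate_dataset(spec)


def neutralize_bn(module):
    """Set every BatchNorm in ``module`` to the exact identity map (eval)."""
    from gcanet import nn

    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.gamma.data[...] = 1.0
            m.beta.data[...] = 0.0
            m.running_mean[...] = 0.0
            m.running_var[...] = 1.0 - m.eps
    module.eval()
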