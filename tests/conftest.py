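import numpy as np
import pytest

from brainmatch.phantom import PhantomConfig, generate_subject, generate_template, generate_visit


@pytest.fixture(scope="session")
def small_cfg():
    """Minimum-size phantom configuration for fast unit tests."""
    return PhantomConfig(shape=(32, 32, 32), seed=7)


@pytest.fixture(scope="session")
def small_template(small_cfg):
    return generate_template(small_cfg)


@pytest.fixture(scope="session")
def small_visit(small_cfg):
    truth = generate_subject(small_cfg, 0)
    return generate_visit(truth, 0, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
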