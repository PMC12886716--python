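import numpy as np
import pytest

from virtmihc.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom with a couple of vessels and a dozen nuclei."""
    return generate_phantom(64, 64, PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Randomly initialized tiny model bundle (base width 8)."""
    from virtmihc.model import ModelBundle
    from virtmihc.training import make_config
    cfg = make_config("tiny", steps=4, seed=3)
    return ModelBundle.create(cfg.model_config(), np.random.default_rng(42))
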