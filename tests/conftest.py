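import numpy as np
import pytest
from hypothesis import settings

from circlink import FixtureSpec, TrainConfig, generate_bundle

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small planted-structure bundle for fast pipeline tests."""
    return generate_bundle(
        FixtureSpec(m=60, n=20, rank=2, density=0.08, n_mirna=40, n_gene=30, seed=11)
    )


@pytest.fixture(scope="session")
def fast_cfg():
    """Short training schedule: enough epochs to move losses, fast to run."""
    return TrainConfig(epochs=40, seed=11, hidden_dim=32, latent_dim=16)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
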