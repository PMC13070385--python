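import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from seq2track.synthetic import WorldConfig, generate_world  # noqa: E402


@pytest.fixture(scope="session")
def micro_world():
    """A very small synthetic world for fast unit tests (not for learning)."""
    cfg = WorldConfig.tiny(seed=11, n_windows_reference=48, n_windows_species=24,
                           n_pretrain_tasks=3, n_duplications=4)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def micro_ref_dataset(micro_world):
    return micro_world.dataset("reference")


@pytest.fixture(scope="session")
def micro_sp_dataset(micro_world):
    return micro_world.dataset("transfer")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
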