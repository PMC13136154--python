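import dataclasses

import numpy as np
import pytest

from ccfocus.phantom import PhantomConfig, generate_case


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def canonical_config():
    """Default geometry with pose jitter disabled (canonical pose)."""
    return dataclasses.replace(PhantomConfig(), pose_rotation_deg=0.0,
                               pose_translation_px=0.0)


@pytest.fixture(scope="session")
def normal_case(default_config):
    return generate_case(default_config, "normal", seed=7)


@pytest.fixture(scope="session")
def agenesis_case(default_config):
    return generate_case(default_config, "agenesis", seed=7)


@pytest.fixture(scope="session")
def canonical_normal(canonical_config):
    return generate_case(canonical_config, "normal", seed=7)


@pytest.fixture(scope="session")
def canonical_agenesis(canonical_config):
    return generate_case(canonical_config, "agenesis", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
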