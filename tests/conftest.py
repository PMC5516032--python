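import numpy as np
import pytest

from stdpmem import LIFParams, STDPConfig, Profile, build_network


@pytest.fixture(scope="session")
def ar_config() -> STDPConfig:
    return STDPConfig(profile=Profile.AR)


@pytest.fixture(scope="session")
def sr_config() -> STDPConfig:
    return STDPConfig(profile=Profile.SR)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def quiet_params(**overrides) -> LIFParams:
    """LIF constants with membrane noise off (deterministic tests)."""
    kw = dict(noise_sigma=0.0)
    kw.update(overrides)
    return LIFParams(**kw)


@pytest.fixture()
def tiny_network():
    """A small fully connected deterministic network, mid-range weights."""
    return build_network(
        n_in=4, n_out=3, p_connect=1.0, w_mean=0.5, w_sd=0.0,
        seed=7, params=quiet_params(),
    )
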