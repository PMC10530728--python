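import numpy as np
import pytest

from microbias import ReplicateSpec, URT_TOP5, synthesize_mean_abundances


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pinned_profile():
    """J=200 community with the five printed top mean abundances pinned."""
    return synthesize_mean_abundances(200, np.random.default_rng(1), URT_TOP5)


@pytest.fixture(scope="session")
def small_profile():
    """J=30 community for fast end-to-end runs."""
    return synthesize_mean_abundances(30, np.random.default_rng(2), URT_TOP5)


@pytest.fixture
def small_spec(small_profile):
    return ReplicateSpec(profile=small_profile, scheme="M2", beta=1.0, phi=1.0)
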