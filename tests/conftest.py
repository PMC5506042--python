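import numpy as np
import pytest

from dualeigen import SimulationSpec, compute_svd, fix_signs, generate_profile


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated study, reused across read-only tests."""
    profile, truth = generate_profile(SimulationSpec(seed=7))
    return profile, truth


@pytest.fixture(scope="session")
def default_decompositions(default_sim):
    profile, truth = default_sim
    pooled = fix_signs(compute_svd(profile), profile.attributes, "week")
    control_profile = profile.control_only()
    control = fix_signs(compute_svd(control_profile), control_profile.attributes, "week")
    return pooled, control


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
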