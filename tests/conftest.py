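import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across read-only tests."""
    from cd8pet.synthetic import GeneratorParams, generate_cohort

    return generate_cohort(GeneratorParams(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    from cd8pet.synthetic import GeneratorParams, generate_cohort

    return generate_cohort(GeneratorParams(n_patients=12, seed=7))
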