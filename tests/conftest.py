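import pytest
from hypothesis import HealthCheck, settings

from mamsrb import DesignSpec, solve_information

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tailor_spec():
    """Four telmisartan-style doses vs control, equal weights, rho = 0.4."""
    return DesignSpec(n_arms=4, delta=0.545, delta0=0.178, rho=0.4)


@pytest.fixture(scope="session")
def tailor_design(tailor_spec):
    """Solved single-stage design shared across tests (deterministic)."""
    return solve_information(tailor_spec)
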