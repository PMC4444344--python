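import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150526)


@pytest.fixture(scope="session")
def noisefree_experiment():
    """One noise-free simulated repression experiment (shared, read-only)."""
    from luxrep import HillParams, simulate

    return simulate.simulate_repression_experiment(
        hill=HillParams(delta=0.05, vmax=2.0, km=2.0, eta=1.5), seed=42
    )
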