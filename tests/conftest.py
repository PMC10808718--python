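import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    from faceloop import SimulationConfig

    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def hrf():
    from faceloop import build_chrf

    return build_chrf(tr=1.0, dt=0.1)


@pytest.fixture(scope="session")
def noiseless_run():
    """One deterministic closed-loop run without any noise source."""
    from faceloop import GroupSpec, SimulationConfig, default_neural_params, simulate_run_closed_loop

    cfg = SimulationConfig(obs_noise_sd=0.0, neural_noise_sd=0.0)
    return simulate_run_closed_loop(
        default_neural_params(), GroupSpec("happy", "up"), cfg, seed=3,
        regulation_effort=0.3,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2 participants per group, reference scenario (fast shared fixture)."""
    from faceloop import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_per_group=2, seed=77))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240111)
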