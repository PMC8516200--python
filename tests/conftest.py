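import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trace():
    from fixtof import simulate, tof_model

    spec = simulate.SyntheticTofSpec(
        tau=2.5, amplitude=40.0, offset=5.0, noise_sd=0.0,
        position_jitter_sd=0.0, seed=0,
    )
    return tof_model.spatial_average(simulate.simulate_tof_trace(spec))


@pytest.fixture(scope="session")
def noisy_fit():
    """A seeded noisy exponential fit with meaningful residual variance."""
    from fixtof import tof_model

    rng = np.random.default_rng(11)
    t = np.linspace(0.0, 6.0, 25)
    y = 40.0 * np.exp(-t / 2.5) + 5.0 + rng.normal(0, 0.5, t.size)
    return t, y, tof_model.fit_exponential(t, y)


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty seeded traces under the default instrument conditions."""
    from fixtof import simulate

    return simulate.simulate_cohort(n=20, seed=7)
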