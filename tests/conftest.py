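import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import circaflux as cf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env() -> pd.DataFrame:
    """Default protocol: 5 entrainment days + 48 h constant, 12 min step."""
    return cf.generate_environment()


@pytest.fixture(scope="session")
def protocol() -> cf.ProtocolConfig:
    return cf.ProtocolConfig()


@pytest.fixture(scope="session")
def dataset() -> dict:
    """One full two-species synthetic dataset at a fixed seed."""
    return cf.generate_dataset(seed=7)


@pytest.fixture()
def noiseless_truth() -> cf.TrueParams:
    return cf.TrueParams(
        noise_sd_leaf=0.0, noise_sd_gs=0.0, noise_sd_canopy=0.0, noise_sd_e=0.0,
    )


def ar1_series(rng: np.random.Generator, n: int, rho: float, sd: float = 1.0) -> np.ndarray:
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e
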