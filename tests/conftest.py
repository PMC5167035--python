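import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from covsync.model import Partition
from covsync.priors import PriorConfig
from covsync.simulate import SimulationScenario, generate, preset_scenarios


@pytest.fixture(scope="session")
def priors():
    return PriorConfig()


@pytest.fixture(scope="session")
def small_panel():
    """A compact 3-species panel with known ground truth (deterministic)."""
    scen = dataclasses.replace(
        preset_scenarios()["tit-like"], n_sites=8, n_years=6, seed=42
    )
    data, truth = generate(scen)
    return data, truth, scen


@pytest.fixture(scope="session")
def two_species_panel():
    """Tiny 2-species panel used by the brute-force model oracles."""
    scen = SimulationScenario(
        name="toy2",
        species=["a", "b"],
        n_sites=4,
        n_years=3,
        max_start_lag=0,
        alpha=[0.05, 0.05],
        sigma2_eps=0.002,
        sigma2_s=[0.002, 0.002],
        gamma={0: (Partition([[0], [1]]), [0.15, 0.0])},
        phi=(Partition([[0, 1]]), [0.3]),
        p=(Partition([[0, 1]]), [1.5]),
        seed=11,
    )
    data, truth = generate(scen)
    return data, truth, scen


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
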