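from dataclasses import replace

import pytest

from epskinetics import (
    GrowthParams,
    ProductParams,
    Scenario,
    default_scenarios,
    generate_timecourse,
)


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def heat_scenario(scenarios):
    return scenarios["heat_stress"]


@pytest.fixture(scope="session")
def normal_scenario(scenarios):
    return scenarios["normal"]


@pytest.fixture()
def exact_timecourse(heat_scenario):
    """Noise-free triplicate course: observations equal the closed forms."""
    return generate_timecourse(replace(heat_scenario, noise_cv=0.0), "exact")


@pytest.fixture()
def noisy_timecourse(heat_scenario):
    return generate_timecourse(replace(heat_scenario, seed=42), "noisy")


@pytest.fixture()
def simple_gp():
    return GrowthParams(X0=0.1, Xmax=8.0, mu_max=0.33528)


@pytest.fixture()
def simple_pp():
    return ProductParams(P0=0.05, alpha=0.3, beta=0.5)
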