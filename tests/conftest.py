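import pytest

from carboxyfe.synthetic_data import (StrainPairSpec, generate_strain_pair,
                                      scenario_preset, simulate_culture)


@pytest.fixture(scope="session")
def strain_pair():
    """Default synthetic strain pair (shared across genome-screen tests)."""
    return generate_strain_pair(StrainPairSpec())


@pytest.fixture(scope="session")
def ferrihydrite_ts():
    return simulate_culture(scenario_preset("ferrihydrite_CO_lactate"))


@pytest.fixture(scope="session")
def glauconite_ts():
    return simulate_culture(scenario_preset("glauconite_CO_lactate"))
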