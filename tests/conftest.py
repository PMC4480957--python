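import pytest

from mechanista import run_pipeline, scenario_config, simulate_scenario


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic scenario: 20 loci, one planted mechanism each."""
    return simulate_scenario(scenario_config(seed=11))


@pytest.fixture(scope="session")
def result(bundle):
    return run_pipeline(bundle)


@pytest.fixture()
def config():
    return scenario_config(seed=11)
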