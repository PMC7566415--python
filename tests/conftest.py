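import pytest
from hypothesis import HealthCheck, settings

from hhsim.hh_library import HHParameters, build_hh_model
from hhsim.simulation import ExperimentConfig, run_modular, run_monolithic

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return HHParameters()


@pytest.fixture()
def model(params):
    return build_hh_model(params)


@pytest.fixture()
def flat(model):
    return model.flatten()


@pytest.fixture(scope="session")
def rest_trace():
    """Modular run at rest: no stimulus, no clamp current, 6.3 °C, 50 ms."""
    return run_modular(ExperimentConfig(v_init=0.0, i_const=0.0))


@pytest.fixture(scope="session")
def ap_traces():
    """Stimulated action potential (v_init = -15 mV) in both formulations."""
    config = ExperimentConfig(v_init=-15.0, i_const=0.0)
    return run_modular(config), run_monolithic(config)
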