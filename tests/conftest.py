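import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    from txa_cea.params import default_parameters

    return default_parameters()


@pytest.fixture(scope="session")
def life_table(params):
    from txa_cea.survival import load_life_table

    return load_life_table(params.life_table)


@pytest.fixture(scope="session")
def base_result(params, life_table):
    from txa_cea.model import run_base_case

    return run_base_case(params, life_table)
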