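import pytest

from crcscreen import (
    base_case_parameter_set,
    builtin_strategies,
    cea_table,
    default_life_table,
    run_cohort,
)


@pytest.fixture(scope="session")
def base_params():
    return base_case_parameter_set()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_results(base_params, life_table):
    """Base-case lifetime runs of all four strategies, shared across tests."""
    return {
        s.name: run_cohort(base_params, s, life_table)
        for s in builtin_strategies(base_params.econ)
    }


@pytest.fixture(scope="session")
def base_cea(base_results):
    return cea_table(list(base_results.values()))
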