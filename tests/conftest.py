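import pytest

from sepsis_cea import default_base_case, default_life_table


@pytest.fixture(scope="session")
def base_config():
    return default_base_case()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture()
def config(base_config):
    """A mutable copy of the base case for tests that modify it."""
    import copy

    return copy.deepcopy(base_config)
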