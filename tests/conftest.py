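import pytest

import smadscreen as ss


@pytest.fixture(scope="session")
def param_fixtures():
    """The shipped, oracle-confirmed parameter sets (one per response family)."""
    return ss.make_parameter_fixtures()


@pytest.fixture(scope="session")
def sustained_ps(param_fixtures):
    return param_fixtures["sustained"]


@pytest.fixture(scope="session")
def transient_ps(param_fixtures):
    return param_fixtures["transient"]


@pytest.fixture(scope="session")
def oscillatory_ps(param_fixtures):
    return param_fixtures["oscillatory"]


@pytest.fixture(scope="session")
def default_cfg():
    return ss.ClassifierConfig()
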