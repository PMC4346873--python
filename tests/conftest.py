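import pytest

from herbnet.adme import RescueRule
from herbnet.synthetic import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def it_edges():
    return load_fixture("it_edges")


@pytest.fixture(scope="session")
def metabolite_map():
    return load_fixture("metabolite_map")


@pytest.fixture(scope="session")
def rescue_rules():
    """The shipped rescue configuration: content rescue at 7.0 mg/g plus
    metabolite rescue with OB+Caco-2 relaxed criteria."""
    return [
        RescueRule("content_rescue", content_min=7.0),
        RescueRule("metabolite_rescue", relaxed=("ob", "caco2")),
    ]
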