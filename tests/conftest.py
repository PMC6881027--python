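import pytest

from ddidetect import rules as rules_mod
from ddidetect.resources import default_rules_path, load_default_resources


@pytest.fixture(scope="session")
def resources():
    return load_default_resources()


@pytest.fixture(scope="session")
def onto(resources):
    return resources.ontology


@pytest.fixture(scope="session")
def default_rules(onto):
    return rules_mod.load_rules(default_rules_path(), onto)
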