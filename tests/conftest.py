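import pytest

from namloc import FrameworkConfig
from namloc.bioactivity import CapabilityMap, SeverityLexicon


@pytest.fixture(scope="session")
def config():
    return FrameworkConfig()


@pytest.fixture(scope="session")
def lexicon():
    return SeverityLexicon.default()


@pytest.fixture(scope="session")
def capability_map():
    return CapabilityMap.default()
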